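"""Split-network algebra for CaO–SiO2–(P2O5) glass compositions.

A glass with per-Si stoichiometry Ca_q Si P_p O_{2+q+5p/2} is partitioned
into a modifier-bearing silicate subnetwork and a calcium orthophosphate
(Ca_{3/2}PO4) reservoir.  Because each orthophosphate unit consumes 3/2 Ca
per P for charge balance, the silicate phase retains q - 3p/2 Ca per Si,
and its average bridging-oxygen (BO) count follows directly: each modifier
Ca2+ converts one Si-O-Si bridge into two non-bridging oxygens, so

    n_BO = 4 - 2*(q - 3p/2) = 8 - 2*m,    m = 2 + q - 3p/2,

where m is the oxygen coefficient of the silicate phase (its average
polymerization degree).  Pure silica (q = p = 0) gives n_BO = 4; a
metasilicate chain (q = 1, p = 0) gives 2.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal

__all__ = [
    "GlassComposition",
    "SplitRepresentation",
    "split_representation",
    "predicted_nbo",
    "oxygen_coefficient",
    "parse_oxide_formula",
    "round_half_up",
]

_CA_P_PER_PHOSPHATE = 1.5  # Ca_{3/2}PO4 stoichiometry; fixed, not a parameter


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as in printed tables (0.0485 -> 0.049)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GlassComposition:
    """Per-Si stoichiometry of a Ca_q Si P_p O_{2+q+5p/2} glass.

    The oxygen coefficient is always derived by charge balance, never stored.
    Surface proton content is ignored.
    """

    label: str
    q: float
    p: float = 0.0
    source: Literal["nominal", "analysed"] = "analysed"

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError(f"{self.label}: Ca coefficient q must be >= 0, got {self.q}")
        if self.p < 0:
            raise ValueError(f"{self.label}: P coefficient p must be >= 0, got {self.p}")

    @property
    def o(self) -> float:
        """Oxygen coefficient 2 + q + 5p/2 from charge balance."""
        return 2.0 + self.q + 2.5 * self.p

    def formula(self) -> str:
        if self.p == 0:
            return f"Ca{self.q:g}SiO{self.o:g}"
        return f"Ca{self.q:g}SiP{self.p:g}O{self.o:g}"


@dataclass(frozen=True)
class SplitRepresentation:
    """Two-phase split: [Ca_c SiO_{2+c}] - p [Ca_{3/2}PO4], c = q - 3p/2."""

    silicate_ca: float
    silicate_o: float
    phosphate_coeff: float

    def __post_init__(self) -> None:
        if abs(self.silicate_o - self.silicate_ca - 2.0) > 1e-12:
            raise ValueError("silicate phase must satisfy O = Ca + 2 (charge balance)")

    def recombine(self, label: str = "recombined") -> GlassComposition:
        """Invert the split; conserves Ca, P and O exactly."""
        p = self.phosphate_coeff
        return GlassComposition(label=label, q=self.silicate_ca + _CA_P_PER_PHOSPHATE * p, p=p)


def oxygen_coefficient(comp: GlassComposition) -> float:
    """Oxygen atoms per Si from charge balance: 2 + q + 5p/2."""
    return comp.o


def split_representation(comp: GlassComposition) -> SplitRepresentation:
    """Partition a composition into silicate and orthophosphate phases.

    Raises
    ------
    ValueError
        If q < 3p/2, i.e. the orthophosphate Ca demand exceeds the Ca
        inventory (the entire Ca reservoir sits in the phosphate phase
        when q ~ 3p/2; beyond that the split is undefined).
    """
    c = comp.q - _CA_P_PER_PHOSPHATE * comp.p
    if c < -1e-12:
        raise ValueError(
            f"{comp.label}: orthophosphate Ca demand exceeds Ca inventory "
            f"(q = {comp.q} < 3p/2 = {_CA_P_PER_PHOSPHATE * comp.p})"
        )
    c = max(c, 0.0)
    return SplitRepresentation(silicate_ca=c, silicate_o=2.0 + c, phosphate_coeff=comp.p)


def predicted_nbo(comp: GlassComposition) -> float:
    """Average bridging oxygens per silicate tetrahedron from composition.

    n_BO = 4 - 2*(q - 3p/2): each silicate-phase Ca2+ removes one bridge,
    creating two NBOs.  Valid while the silicate subnetwork lies between
    pure Q4 silica (q - 3p/2 = 0) and fully depolymerized Q0 (= 2).
    """
    c = split_representation(comp).silicate_ca
    if c > 2.0 + 1e-12:
        raise ValueError(
            f"{comp.label}: silicate-phase Ca per Si = {c:.4g} exceeds 2, "
            "the fully depolymerized (Q0) limit"
        )
    return 4.0 - 2.0 * c


_OXIDE_RE = re.compile(r"(\d+(?:\.\d+)?)\s*(CaO|SiO2|P2O5)", re.IGNORECASE)


def parse_oxide_formula(text: str, label: str = "", source: str = "nominal") -> GlassComposition:
    """Parse oxide-equivalent notation like ``"10CaO-85SiO2-5P2O5"``.

    Molar oxide fractions are normalized to per-Si coefficients:
    q = CaO/SiO2 and p = 2*P2O5/SiO2 (two P per P2O5 unit).
    """
    found: dict[str, float] = {}
    for m in _OXIDE_RE.finditer(text):
        key = m.group(2).upper().replace("O2", "O2").replace("2O5", "2O5")
        found[m.group(2).upper()] = float(m.group(1))
    si = found.get("SIO2", 0.0)
    if si <= 0:
        raise ValueError(f"cannot parse oxide formula {text!r}: no SiO2 term")
    return GlassComposition(
        label=label or text,
        q=found.get("CAO", 0.0) / si,
        p=2.0 * found.get("P2O5", 0.0) / si,
        source=source,  # type: ignore[arg-type]
    )
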
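"""Qn species assignment and the NMR-derived network-connectivity statistic.

A silicate tetrahedron with n bridging oxygens resonates ~10 ppm apart from
its n+1 neighbour, so fitted peak centers map to species through chemical
shift windows.  Two complications drive the design here:

* protonated (silanol) species Q3_H and Q2_H are surface artefacts that the
  composition-based connectivity argument does not account for, so the
  NMR-derived average BO count is computed over the {Q4, Qn_Ca} subset only,
  renormalized to a unit sum;
* the Q2_H and Q3_Ca resonances overlap near -91 ppm and usually cannot be
  resolved, so that peak carries an attribution policy: wholly Q2_H for
  Ca-poor glasses, shared (typically 50/50) with Q3_Ca for Ca-rich ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

import pandas as pd

from .errors import AnalysisError

if TYPE_CHECKING:  # pragma: no cover
    from .deconvolution import FitResult

__all__ = [
    "SPECIES",
    "MERGED",
    "BO_COUNT",
    "SpeciesRecord",
    "SpeciationTable",
    "AssignmentPolicy",
    "assign_species",
    "nmr_nbo",
    "mean_bo_from_fractions",
    "compare_connectivity",
]

#: merged, spectrally unresolved Q2_H + Q3_Ca peak near -91 ppm
MERGED = "Q2H_Q3Ca"

#: recognised species labels
SPECIES = ("Q4", "Q3_H", "Q2_H", "Q3_Ca", "Q2_Ca", "Q1_Ca", MERGED)

#: bridging oxygens per tetrahedron for the unambiguous species
BO_COUNT = {"Q4": 4, "Q3_H": 3, "Q2_H": 2, "Q3_Ca": 3, "Q2_Ca": 2, "Q1_Ca": 1}

#: species excluded from the connectivity estimate (proton-compensated)
_PROTONATED = {"Q3_H", "Q2_H"}


@dataclass(frozen=True)
class SpeciesRecord:
    species: str
    delta_ppm: float
    fwhm_ppm: float
    fraction_pct: float
    sd_pct: float | None = None

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species label {self.species!r}")


@dataclass
class SpeciationTable:
    """Fractional Qn populations of one sample, one acquisition mode.

    Fractions are percentages closing to 100 within ``closure_tol``
    (default 0.2 to absorb printed rounding).
    """

    sample: str
    records: list[SpeciesRecord]
    mode: str = "single_pulse"
    closure_tol: float = 0.2

    def __post_init__(self) -> None:
        if self.mode not in ("single_pulse", "cpmas"):
            raise ValueError(f"mode must be single_pulse or cpmas, got {self.mode!r}")
        total = sum(r.fraction_pct for r in self.records)
        if abs(total - 100.0) > self.closure_tol + 1e-9:
            raise ValueError(
                f"{self.sample}: fractions sum to {total:.2f}, not 100 +/- {self.closure_tol}"
            )
        seen = [r.species for r in self.records]
        if len(seen) != len(set(seen)):
            raise ValueError(f"{self.sample}: duplicate species in table")

    def fractions(self) -> dict[str, float]:
        return {r.species: r.fraction_pct for r in self.records}

    def fraction(self, species: str, default: float = 0.0) -> float:
        for r in self.records:
            if r.species == species:
                return r.fraction_pct
        return default

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample": self.sample,
                    "species": r.species,
                    "delta_ppm": r.delta_ppm,
                    "fwhm_ppm": r.fwhm_ppm,
                    "fraction_pct": r.fraction_pct,
                    "sd_pct": r.sd_pct,
                    "mode": self.mode,
                }
                for r in self.records
            ]
        )


#: default half-open shift windows (lo < delta <= hi), ppm
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "Q4": (-120.0, -105.0),
    "Q3_H": (-105.0, -97.0),
    MERGED: (-97.0, -87.0),
    "Q2_Ca": (-87.0, -79.0),
    "Q1_Ca": (-79.0, -71.0),
}


@dataclass(frozen=True)
class AssignmentPolicy:
    """Shift windows plus the merged-peak sharing rule.

    ``merged_sharing`` is the fraction of the ~-91 ppm peak attributed to
    Q3_Ca (0 for Ca-poor glasses where it is wholly Q2_H; 0.5 for Ca-rich
    ones where both species contribute).
    """

    windows: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS)
    )
    merged_sharing: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.merged_sharing <= 1.0:
            raise ValueError(f"merged_sharing must be in [0, 1], got {self.merged_sharing}")
        spans = sorted(self.windows.items(), key=lambda kv: kv[1][0])
        for (s1, w1), (s2, w2) in zip(spans, spans[1:]):
            if w1[1] > w2[0]:
                raise ValueError(f"windows for {s1} and {s2} overlap")

    def merged_label(self) -> str:
        """Species label carried by the merged window under this policy."""
        if self.merged_sharing == 0.0:
            return "Q2_H"
        if self.merged_sharing == 1.0:
            return "Q3_Ca"
        return MERGED

    def species_at(self, delta_ppm: float) -> str:
        for species, (lo, hi) in self.windows.items():
            if lo < delta_ppm <= hi:
                return self.merged_label() if species == MERGED else species
        raise AnalysisError(
            f"peak at {delta_ppm:.1f} ppm falls outside every assignment window"
        )


def assign_species(fit: "FitResult", policy: AssignmentPolicy, sample: str = "",
                   mode: str = "single_pulse") -> SpeciationTable:
    """Label fitted components by shift window and convert areas to fractions."""
    total = sum(c.area for c in fit.components)
    if total <= 0:
        raise AnalysisError(f"{sample or 'fit'}: total fitted area is zero")
    records = []
    for c in fit.components:
        records.append(
            SpeciesRecord(
                species=policy.species_at(c.center),
                delta_ppm=c.center,
                fwhm_ppm=c.fwhm,
                fraction_pct=100.0 * c.area / total,
            )
        )
    return SpeciationTable(sample=sample or fit.label, records=records, mode=mode)


def mean_bo_from_fractions(fractions: Mapping[str, float], merged_sharing: float = 0.0) -> float:
    """Average bridging-oxygen count over the {Q4, Qn_Ca} subset.

    Protonated species are dropped; a merged Q2_H/Q3_Ca entry contributes
    ``merged_sharing`` of its fraction as Q3_Ca; the survivors are
    renormalized to a unit sum before the n-weighted mean.  Invariant under
    uniform rescaling of all fractions.
    """
    weights: dict[str, float] = {}
    for species, f in fractions.items():
        if f < 0:
            raise ValueError(f"negative fraction for {species}")
        if species == MERGED:
            weights["Q3_Ca"] = weights.get("Q3_Ca", 0.0) + merged_sharing * f
        elif species in _PROTONATED:
            continue
        elif species in BO_COUNT:
            weights[species] = weights.get(species, 0.0) + f
        else:
            raise ValueError(f"unknown species label {species!r}")
    total = sum(weights.values())
    if total <= 0:
        raise AnalysisError("no Q4 or Qn_Ca population to average over")
    return sum(BO_COUNT[s] * w for s, w in weights.items()) / total


def nmr_nbo(table: SpeciationTable, policy: AssignmentPolicy) -> float:
    """NMR-derived average BO number for one speciation table."""
    if table.fraction("Q4") <= 0:
        raise AnalysisError(f"{table.sample}: no Q4 entry; connectivity estimate undefined")
    return mean_bo_from_fractions(table.fractions(), policy.merged_sharing)


def compare_connectivity(derived: float, predicted: float) -> float:
    """Relative deviation (%) of the NMR-derived BO count from the predicted one."""
    if predicted <= 0:
        raise ValueError(f"predicted BO count must be > 0, got {predicted}")
    return 100.0 * abs(derived - predicted) / predicted
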
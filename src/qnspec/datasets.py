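"""Bundled reference data for the three CaO-SiO2-(P2O5) mesoporous glasses.

Three CSVs ship with the package: XRF-derived per-Si compositions of the
S90, S85 and S58 glasses (nominal and analysed), and their single-pulse and
CPMAS 29Si speciation tables over the SBF soaking series (0 to 168 h).
These are the published deconvolution results; synthetic spectra are
generated from them when raw traces are needed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .composition import GlassComposition
from .io import tables_from_frame
from .sbf import SoakingSeries
from .speciation import AssignmentPolicy, SpeciationTable

__all__ = [
    "load_compositions",
    "load_speciation",
    "pristine_table",
    "load_series",
    "default_policy",
    "SAMPLES",
]

SAMPLES = ("S90", "S85", "S58")

#: merged -91 ppm peak attribution: wholly Q2_H for the Ca-poor glasses,
#: shared 50/50 with Q3_Ca for Ca-rich S58
MERGED_SHARING = {"S90": 0.0, "S85": 0.0, "S58": 0.5}


def _read(name: str) -> pd.DataFrame:
    with resources.files("qnspec.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_compositions(source: str = "analysed") -> dict[str, GlassComposition]:
    """Per-Si glass compositions, keyed by sample label."""
    df = _read("compositions.csv")
    df = df[df["source"] == source]
    return {
        r.label: GlassComposition(label=r.label, q=float(r.q), p=float(r.p), source=source)
        for r in df.itertuples()
    }


def load_speciation(mode: str = "single_pulse") -> dict[tuple[str, float], SpeciationTable]:
    """All speciation tables of one acquisition mode, keyed by (sample, tau_hours)."""
    name = "single_pulse_speciation.csv" if mode == "single_pulse" else "cpmas_speciation.csv"
    return tables_from_frame(_read(name))


def pristine_table(sample: str, mode: str = "single_pulse") -> SpeciationTable:
    """The tau = 0 speciation table of one sample."""
    return load_speciation(mode)[(sample, 0.0)]


def load_series(sample: str, mode: str = "cpmas") -> SoakingSeries:
    """The full soaking series of one sample as an ordered SoakingSeries."""
    tables = load_speciation(mode)
    points = sorted(
        ((tau, tab) for (s, tau), tab in tables.items() if s == sample),
        key=lambda p: p[0],
    )
    if not points:
        raise KeyError(f"no {mode} tables for sample {sample!r}")
    return SoakingSeries(label=sample, points=points, mode=mode)


def default_policy(sample: str) -> AssignmentPolicy:
    """Default shift windows with the sample's merged-peak sharing factor."""
    return AssignmentPolicy(merged_sharing=MERGED_SHARING.get(sample, 0.0))
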
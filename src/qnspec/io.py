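"""Readers and writers: two-column ASCII spectra and speciation CSVs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .lineshape import Spectrum
from .speciation import SpeciationTable, SpeciesRecord

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_speciation_frame",
    "write_speciation_frame",
    "tables_from_frame",
    "frame_from_tables",
]

_SPECIATION_COLUMNS = ["sample", "tau_hours", "species", "delta_ppm",
                       "fwhm_ppm", "fraction_pct", "sd_pct", "mode"]


def read_spectrum(path: str | Path, label: str = "") -> Spectrum:
    """Read a two-column (ppm, intensity) ASCII file; '#' lines are comments.

    Ascending-axis files are reversed to the descending storage convention.
    Ragged rows and non-uniform axes raise FormatError with the line number.
    """
    path = Path(path)
    ppm: list[float] = []
    inten: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            ppm.append(float(parts[0]))
            inten.append(float(parts[1]))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric value ({exc})") from None
    x = np.asarray(ppm)
    y = np.asarray(inten)
    if x.size < 2:
        raise FormatError(f"{path}: too few data rows ({x.size})")
    steps = np.diff(x)
    if np.all(steps > 0):
        x, y = x[::-1], y[::-1]
        steps = np.diff(x)
    if not np.all(steps < 0):
        bad = int(np.argmax(steps >= 0)) + 1
        raise FormatError(f"{path}: ppm axis not monotone near data row {bad}")
    if not np.allclose(steps, steps[0], rtol=0, atol=1e-6 * abs(steps[0])):
        bad = int(np.argmax(~np.isclose(steps, steps[0], rtol=0, atol=1e-6 * abs(steps[0])))) + 1
        raise FormatError(f"{path}: ppm axis not uniform near data row {bad}")
    try:
        return Spectrum(ppm=x, intensity=y, label=label or path.stem)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column ASCII, lossless to ~1e-12 relative."""
    path = Path(path)
    with path.open("w") as fh:
        if spectrum.label:
            fh.write(f"# {spectrum.label}\n")
        fh.write("# ppm intensity\n")
        for x, y in zip(spectrum.ppm, spectrum.intensity):
            fh.write(f"{x:.12g} {y:.12g}\n")


def read_speciation_frame(path: str | Path) -> pd.DataFrame:
    """Read a speciation CSV (schema: sample, tau_hours, species, delta_ppm,
    fwhm_ppm, fraction_pct, sd_pct, mode)."""
    df = pd.read_csv(path)
    missing = [c for c in _SPECIATION_COLUMNS if c not in df.columns and c not in ("tau_hours", "sd_pct")]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    if "tau_hours" not in df.columns:
        df["tau_hours"] = 0.0
    if "sd_pct" not in df.columns:
        df["sd_pct"] = np.nan
    return df[_SPECIATION_COLUMNS]


def write_speciation_frame(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def tables_from_frame(df: pd.DataFrame) -> dict[tuple[str, float], SpeciationTable]:
    """Group a tidy speciation frame into per-(sample, tau) tables."""
    out: dict[tuple[str, float], SpeciationTable] = {}
    for (sample, tau), grp in df.groupby(["sample", "tau_hours"], sort=False):
        mode = grp["mode"].iloc[0]
        records = [
            SpeciesRecord(
                species=r.species,
                delta_ppm=float(r.delta_ppm),
                fwhm_ppm=float(r.fwhm_ppm),
                fraction_pct=float(r.fraction_pct),
                sd_pct=None if pd.isna(r.sd_pct) else float(r.sd_pct),
            )
            for r in grp.itertuples()
        ]
        out[(sample, float(tau))] = SpeciationTable(sample=sample, records=records, mode=mode)
    return out


def frame_from_tables(tables: dict[tuple[str, float], SpeciationTable]) -> pd.DataFrame:
    frames = []
    for (sample, tau), tab in tables.items():
        f = tab.to_frame()
        f.insert(1, "tau_hours", tau)
        frames.append(f)
    return pd.concat(frames, ignore_index=True)[_SPECIATION_COLUMNS]
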
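"""Surface-speciation bookkeeping over simulated-body-fluid soaking series.

During SBF immersion the surface silicate speciation evolves through three
schematic reactions: release of surface Ca2+ (loss of Qn_Ca units),
Ca2+ <-> H+ exchange converting Q2_Ca into geminal-silanol Q2_H, and
silanol condensation 2 Q2_H -> Q3_H + H2O.  The net effect is classified
from the full-span change of the (Q4 + Q3_H) population: a gain beyond the
fraction uncertainty is a repolymerization of the surface network, a
mirrored loss a depolymerization.  No kinetics are fitted — the reactions
are bookkeeping categories, not rate laws.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

from .errors import AnalysisError
from .speciation import MERGED, SpeciationTable

__all__ = [
    "SoakingSeries",
    "NetProcess",
    "ReactionEvidence",
    "delta_populations",
    "group_balance",
    "classify_net_process",
    "series_frame",
    "plot_series",
]

#: species whose gain marks network condensation
_GAIN_GROUP = ("Q4", "Q3_H")
#: low-connectivity / Ca-associated species (the merged peak belongs here
#: under either attribution, so no sharing policy is needed)
_LOSS_GROUP = ("Q2_H", "Q2_Ca", "Q1_Ca", "Q3_Ca", MERGED)

#: explicit Ca-compensated species used for the Ca-release evidence flag
_CA_GROUP = ("Q3_Ca", "Q2_Ca", "Q1_Ca")


class NetProcess(enum.Enum):
    REPOLYMERIZATION = "repolymerization"
    DEPOLYMERIZATION = "depolymerization"
    STATIONARY = "stationary"


@dataclass(frozen=True)
class ReactionEvidence:
    """Per-reaction evidence flags for the schematic surface reactions."""

    ca_release: bool          # Qn_Ca populations drop (Ca2+ dissolution)
    ca_proton_exchange: bool  # early Q2_H rise (Q2_Ca -> Q2_H conversion)
    silanol_condensation: bool  # Q3_H gain with Q2_H loss (2 Q2_H -> Q3_H)


@dataclass
class SoakingSeries:
    """Ordered (tau_SBF, speciation) points for one glass system; tau in hours."""

    label: str
    points: list[tuple[float, SpeciationTable]]
    mode: str = "cpmas"

    def __post_init__(self) -> None:
        taus = [t for t, _ in self.points]
        if any(t < 0 for t in taus):
            raise ValueError(f"{self.label}: tau_SBF must be >= 0 hours")
        if any(b <= a for a, b in zip(taus, taus[1:])):
            raise ValueError(f"{self.label}: tau values must be strictly increasing")
        for _, tab in self.points:
            if tab.mode != self.mode:
                raise ValueError(
                    f"{self.label}: table mode {tab.mode!r} differs from series mode {self.mode!r}"
                )

    @property
    def taus(self) -> list[float]:
        return [t for t, _ in self.points]

    def table_at(self, tau: float) -> SpeciationTable:
        for t, tab in self.points:
            if t == tau:
                return tab
        raise KeyError(f"{self.label}: no time point at tau = {tau} h (have {self.taus})")

    def species(self) -> list[str]:
        """Union of species over all points (late points may drop depleted ones)."""
        seen: list[str] = []
        for _, tab in self.points:
            for r in tab.records:
                if r.species not in seen:
                    seen.append(r.species)
        return seen


def delta_populations(series: SoakingSeries, species: str, t0: float, t1: float) -> float:
    """Signed change (percentage units) of one species between two time points.

    A species absent from a table counts as 0% (fully depleted).
    """
    return series.table_at(t1).fraction(species) - series.table_at(t0).fraction(species)


def group_balance(series: SoakingSeries, t0: float | None = None, t1: float | None = None
                  ) -> tuple[float, float]:
    """(gain of Q4+Q3_H, loss of low-connectivity species) between t0 and t1.

    Because fractions are compositional, the two sums cancel exactly when
    every table closes to exactly 100%; printed rounding can leave a
    remainder of a few tenths.
    """
    if t0 is None:
        t0 = series.taus[0]
    if t1 is None:
        t1 = series.taus[-1]
    gain = sum(delta_populations(series, s, t0, t1) for s in _GAIN_GROUP)
    loss = sum(delta_populations(series, s, t0, t1) for s in _LOSS_GROUP)
    return gain, loss


def classify_net_process(
    series: SoakingSeries,
    threshold_pct: float = 2.0,
    early_window_h: float = 24.0,
) -> tuple[NetProcess, ReactionEvidence]:
    """Classify the net surface process over the full soaking span.

    ``threshold_pct`` (default 2 percentage units, the fraction uncertainty
    of the deconvolutions) is the dead band around zero: smaller net changes
    are reported as stationary.  Evidence flags:

    * Ca release — the explicit Qn_Ca populations drop by more than the
      threshold over the full span;
    * Ca2+/H+ exchange — the Q2_H population rises above its pristine value
      by more than the threshold at some point within ``early_window_h``;
    * silanol condensation — Q3_H gains more than the threshold while the
      Q2_H (including merged) population decreases.
    """
    if len(series.points) < 2:
        raise AnalysisError(f"{series.label}: need >= 2 time points to classify")
    t0, t1 = series.taus[0], series.taus[-1]
    net = sum(delta_populations(series, s, t0, t1) for s in _GAIN_GROUP)
    if net > threshold_pct:
        verdict = NetProcess.REPOLYMERIZATION
    elif net < -threshold_pct:
        verdict = NetProcess.DEPOLYMERIZATION
    else:
        verdict = NetProcess.STATIONARY

    ca_loss = sum(delta_populations(series, s, t0, t1) for s in _CA_GROUP)
    q2h0 = series.table_at(t0).fraction("Q2_H") + series.table_at(t0).fraction(MERGED)
    early_rise = max(
        (
            series.table_at(t).fraction("Q2_H") + series.table_at(t).fraction(MERGED) - q2h0
            for t in series.taus
            if 0 < t <= early_window_h
        ),
        default=0.0,
    )
    dq3h = delta_populations(series, "Q3_H", t0, t1)
    dq2h = (
        delta_populations(series, "Q2_H", t0, t1)
        + delta_populations(series, MERGED, t0, t1)
    )
    evidence = ReactionEvidence(
        ca_release=ca_loss < -threshold_pct,
        ca_proton_exchange=early_rise > threshold_pct,
        silanol_condensation=dq3h > threshold_pct and dq2h < 0,
    )
    return verdict, evidence


def series_frame(series: SoakingSeries) -> pd.DataFrame:
    """Tidy (tau_hours, species, fraction_pct) frame; absent species are 0."""
    rows = []
    for t, tab in series.points:
        for s in series.species():
            rows.append(
                {"sample": series.label, "tau_hours": t, "species": s,
                 "fraction_pct": tab.fraction(s), "mode": series.mode}
            )
    return pd.DataFrame(rows)


def plot_series(series: SoakingSeries, ax=None):
    """Fractions against soaking time on a symlog time axis (tau=0 shown)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    df = series_frame(series)
    for s, grp in df.groupby("species", sort=False):
        ax.plot(grp["tau_hours"], grp["fraction_pct"], marker="o", label=s)
    ax.set_xscale("symlog", linthresh=0.5)
    ax.set_xlabel(r"$\tau_\mathrm{SBF}$ (h)")
    ax.set_ylabel("fraction (%)")
    ax.set_title(f"{series.label} ({series.mode})")
    ax.legend(fontsize=8)
    return ax
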
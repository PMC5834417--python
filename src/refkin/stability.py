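"""Time-stability and dynamic-vs-static agreement analyses.

A short scan is cheaper and kinder to patients, but truncating the data or
shifting the static window changes the outcome measure. These sweeps
quantify that: BP_ND refit at shrinking scan durations (SRTM), BP_ND versus
the Logan equilibrium time t*, SUVR versus static-window start, and the
pooled regression of SUVR on BP_ND across regions and subjects.

"Stable" is operationalised as entering — and staying within — a ±5% band
around the full-data estimate (the band is configurable); fast-kinetics
tracers stabilise earlier than slow ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .kinetic_models import (
    DEFAULT_THETA_GRID,
    _SRTMBasis,
    compute_suvr,
    fit_reference_logan,
    fit_srtm,
)
from .tac_io import RegionalTACSet

logger = logging.getLogger(__name__)

__all__ = [
    "StabilityCurve",
    "AgreementResult",
    "MIN_FRAMES_FOR_FIT",
    "bpnd_vs_duration",
    "logan_tstar_sweep",
    "suvr_window_sweep",
    "regress_static_vs_dynamic",
    "stabilization_onset",
    "plot_stability_curve",
]

#: shortest truncated scan considered fittable
MIN_FRAMES_FOR_FIT = 5


@dataclass
class StabilityCurve:
    """Mean ± SD of an outcome per region along a sweep variable."""

    variable: str                    # "duration" | "t_star" | "window_start"
    sweep_values: np.ndarray         # minutes, strictly increasing
    table: pd.DataFrame              # columns: region, sweep, mean, sd
    outcome: str = "BP_ND"

    def region_curve(self, region: str) -> pd.DataFrame:
        sub = self.table[self.table.region == region].sort_values("sweep")
        if sub.empty:
            raise KeyError(f"region {region!r} not in stability table")
        return sub

    @property
    def regions(self) -> list[str]:
        return sorted(self.table.region.unique())


@dataclass
class AgreementResult:
    """Pooled OLS agreement between a static and a dynamic outcome."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    pair: str


def _aggregate(rows: list[tuple], variable: str, outcome: str) -> StabilityCurve:
    df = pd.DataFrame(rows, columns=["region", "sweep", "subject", "value"])
    agg = (
        df.groupby(["region", "sweep"], as_index=False)["value"]
        .agg(mean="mean", sd=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
    )
    sweep_values = np.array(sorted(df.sweep.unique()), dtype=float)
    return StabilityCurve(variable, sweep_values, agg, outcome=outcome)


def bpnd_vs_duration(
    tac_sets: Sequence[RegionalTACSet],
    durations: Sequence[float],
    method: str = "srtm",
    theta_grid: np.ndarray = DEFAULT_THETA_GRID,
) -> StabilityCurve:
    """SRTM BP_ND refit at a series of truncated scan durations.

    Frames straddling a truncation time are dropped, not clipped. Durations
    leaving fewer than :data:`MIN_FRAMES_FOR_FIT` frames are skipped with a
    warning. Returns across-subject mean ± SD per region and duration.
    """
    if method != "srtm":
        raise ValueError("duration sweep is defined for the SRTM method")
    rows = []
    for duration in sorted(set(float(d) for d in durations)):
        for ts in tac_sets:
            try:
                trunc = ts.truncated(duration)
            except ValueError:
                logger.warning("duration %.1f min leaves no frames; skipped", duration)
                continue
            if trunc.schedule.n_frames < MIN_FRAMES_FOR_FIT:
                logger.warning(
                    "duration %.1f min leaves %d < %d frames; skipped",
                    duration, trunc.schedule.n_frames, MIN_FRAMES_FOR_FIT,
                )
                continue
            basis = _SRTMBasis(trunc.reference, theta_grid)
            for region, tac in trunc.targets().items():
                fit = fit_srtm(tac, trunc.reference, _basis=basis)
                rows.append((region, duration, ts.subject, fit.BP_ND))
    if not rows:
        raise ValueError("no duration produced a fittable truncated scan")
    return _aggregate(rows, "duration", "BP_ND")


def logan_tstar_sweep(
    tac_sets: Sequence[RegionalTACSet],
    t_stars: Sequence[float],
) -> StabilityCurve:
    """Reference Logan BP_ND across a range of equilibrium times t*."""
    rows = []
    for t_star in sorted(set(float(t) for t in t_stars)):
        for ts in tac_sets:
            for region, tac in ts.targets().items():
                fit = fit_reference_logan(tac, ts.reference, t_star)
                rows.append((region, t_star, ts.subject, fit.BP_ND))
    return _aggregate(rows, "t_star", "BP_ND")


def suvr_window_sweep(
    tac_sets: Sequence[RegionalTACSet],
    window_starts: Sequence[float],
    width: float = 20.0,
) -> StabilityCurve:
    """SUVR across static windows [start, start + width] of fixed width."""
    rows = []
    for start in sorted(set(float(s) for s in window_starts)):
        for ts in tac_sets:
            res = compute_suvr(ts, (start, start + width))
            for region, value in res.suvr.items():
                rows.append((region, start, ts.subject, value))
    return _aggregate(rows, "window_start", "SUVR")


def regress_static_vs_dynamic(
    suvr: pd.DataFrame,
    bpnd: pd.DataFrame,
    pair: str = "SUVR~BP_ND",
) -> AgreementResult:
    """Pooled OLS of SUVR on BP_ND over matched (subject, region) pairs.

    Inputs are tidy frames with columns (subject, region, value); all pairs
    are pooled jointly — regions are not regressed separately.
    """
    merged = suvr.merge(bpnd, on=["subject", "region"], suffixes=("_suvr", "_bpnd"))
    if len(merged) < 3:
        raise ValueError(f"only {len(merged)} matched (subject, region) pairs; need >= 3")
    x = merged["value_bpnd"].to_numpy(dtype=float)
    y = merged["value_suvr"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("BP_ND values have zero variance; regression undefined")
    fit = linregress(x, y)
    return AgreementResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(merged),
        pair=pair,
    )


def stabilization_onset(
    curve: StabilityCurve,
    region: str,
    band: float = 0.05,
) -> float:
    """Earliest sweep value from which the regional mean stays within
    ±band of its final (longest-sweep) value.

    Returns the sweep value in minutes; raises if the curve never settles
    (i.e. the last point alone is within the band of itself, so the result
    is always defined — at worst the final sweep value).
    """
    sub = curve.region_curve(region)
    final = float(sub["mean"].iloc[-1])
    if final == 0:
        raise ValueError(f"region {region!r}: final estimate is 0; band undefined")
    rel = np.abs(sub["mean"].to_numpy() / final - 1.0)
    inside = rel <= band
    # last index after which all points remain inside the band
    onset_idx = len(inside) - 1
    for i in range(len(inside)):
        if inside[i:].all():
            onset_idx = i
            break
    return float(sub["sweep"].iloc[onset_idx])


def plot_stability_curve(curve: StabilityCurve, path, regions: Sequence[str] | None = None):
    """Mean ± SD versus sweep variable per region (errorbar plot)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for region in regions or curve.regions:
        sub = curve.region_curve(region)
        ax.errorbar(sub["sweep"], sub["mean"], yerr=sub["sd"], marker="o",
                    capsize=3, label=region)
    ax.set_xlabel(f"{curve.variable} (min)")
    ax.set_ylabel(curve.outcome)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
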
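"""Summary diagnostics of the counterfactual analysis.

Seasonal cycle of the percent reduction, longitudinal/latitudinal profiles,
the mean transpired fraction, and a post-rainfall cwv-change check (does
column water vapor drop after a rain event?, a stated approximation — event
definition and windows are configurable defaults, not a reproduction of any
particular published procedure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .counterfactual import ReductionSummary

__all__ = [
    "SeasonalProfile",
    "SpatialProfile",
    "PostEventResult",
    "seasonal_cycle",
    "spatial_profile",
    "mean_transpired_fraction",
    "post_event_cwv_change",
]


@dataclass
class SeasonalProfile:
    """Monthly percent reductions, area-wide.

    ``median`` comes from the q=50 counterfactual; the band edges come from
    the q=25 (upper: larger reduction) and q=75 (lower) counterfactuals,
    each summarized by the median over all (cell, year-month) entries of
    that calendar month.
    """

    month: np.ndarray  # 1..12
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month": self.month,
                "reduction_pct_median": self.median,
                "reduction_pct_lower": self.lower,
                "reduction_pct_upper": self.upper,
            }
        )


@dataclass
class SpatialProfile:
    """Per-column (or per-row) mean annual reduction."""

    axis: str  # "longitude" | "latitude"
    coord: np.ndarray
    reduction_pct: np.ndarray
    decrease_mm_yr: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.axis: self.coord,
                "reduction_pct": self.reduction_pct,
                "decrease_mm_yr": self.decrease_mm_yr,
            }
        )


def seasonal_cycle(summary: ReductionSummary) -> SeasonalProfile:
    """Percent reduction per calendar month, pooled over cells and years."""
    months = np.arange(1, 13)

    def per_month(q: int) -> np.ndarray:
        table = summary.monthly_reduction_table(q)
        med = table.groupby("month")["reduction_pct"].median()
        missing = sorted(set(months.tolist()) - set(med.index.tolist()))
        if missing:
            raise ValueError(f"no complete month with observed precipitation: {missing}")
        return med.reindex(months).to_numpy()

    return SeasonalProfile(
        month=months,
        median=per_month(50),
        lower=per_month(75),  # upper quartile scaling → smallest reduction
        upper=per_month(25),
    )


def spatial_profile(summary: ReductionSummary, axis: str, q: int = 50) -> SpatialProfile:
    """Mean annual reduction per longitude column or latitude row."""
    if axis not in ("longitude", "latitude"):
        raise ValueError(f"axis must be 'longitude' or 'latitude', got {axis!r}")
    pct_map = summary.per_cell_annual_reduction_pct(q)
    mm_map = summary.per_cell_annual_decrease_mm(q)
    keep_dim, other = ("lon", "lat") if axis == "longitude" else ("lat", "lon")
    return SpatialProfile(
        axis=axis,
        coord=pct_map[keep_dim].values,
        reduction_pct=pct_map.mean(other).values,
        decrease_mm_yr=mm_map.mean(other).values,
    )


def mean_transpired_fraction(ft: xr.DataArray) -> float:
    """Area-time mean of f_t, in percent."""
    return float(100.0 * ft.mean())


@dataclass
class PostEventResult:
    """Paired pre/post cwv differences around rain events."""

    deltas: np.ndarray  # mm, post-window mean minus pre-window mean
    n_events: int
    mean_delta: float
    ci_low: float
    ci_high: float


def _cell_deltas(
    w: np.ndarray,
    p: np.ndarray,
    threshold: float,
    window: int,
    min_separation: int,
) -> np.ndarray:
    """Event onsets: hours with p >= threshold and no exceedance in the
    preceding ``min_separation`` hours; delta = mean cwv over the post
    window minus mean over the pre window."""
    hits = np.nonzero(p >= threshold)[0]
    deltas = []
    last = -np.inf
    for t in hits:
        if t - last < min_separation:
            last = t
            continue
        last = t
        if t - window < 0 or t + window >= len(w):
            continue
        pre = w[t - window : t].mean()
        post = w[t + 1 : t + 1 + window].mean()
        deltas.append(post - pre)
    return np.asarray(deltas)


def post_event_cwv_change(
    cwv: xr.DataArray | np.ndarray,
    p: xr.DataArray | np.ndarray,
    event_threshold: float = 1.0,
    window: int = 3,
    min_separation: int = 6,
    n_boot: int = 1000,
    seed: int = 0,
) -> PostEventResult:
    """Change of column water vapor across rain events.

    Pools Δcwv over all cells and events; the summary is the mean delta
    with a seeded bootstrap percentile interval (95%).  Returns an empty
    result (with a warning) when no event qualifies.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1 hour, got {window}")
    w = np.asarray(cwv.values if isinstance(cwv, xr.DataArray) else cwv, dtype=float)
    pr = np.asarray(p.values if isinstance(p, xr.DataArray) else p, dtype=float)
    if w.shape != pr.shape:
        raise ValueError("cwv and p must be aligned")
    if w.ndim == 1:
        w = w[:, None]
        pr = pr[:, None]
    else:
        w = w.reshape(w.shape[0], -1)
        pr = pr.reshape(pr.shape[0], -1)

    all_deltas = [
        _cell_deltas(w[:, c], pr[:, c], event_threshold, window, min_separation)
        for c in range(w.shape[1])
    ]
    deltas = np.concatenate(all_deltas) if all_deltas else np.zeros(0)
    if deltas.size == 0:
        warnings.warn("no rain events found above the threshold", stacklevel=2)
        nan = float("nan")
        return PostEventResult(deltas, 0, nan, nan, nan)

    rng = np.random.default_rng(np.random.SeedSequence([105, seed]))
    boots = np.array(
        [rng.choice(deltas, size=deltas.size, replace=True).mean() for _ in range(n_boot)]
    )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return PostEventResult(
        deltas=deltas,
        n_events=int(deltas.size),
        mean_delta=float(deltas.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
    )
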
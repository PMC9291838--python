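"""Counterfactual precipitation without Amazon tree transpiration.

The counterfactual column water vapor is ``cwv_t = (1 - f_t) * cwv``, with
the monthly transpired fraction f_t applied uniformly to all hours of the
calendar month.  Observed precipitation is then scaled per hour by the
quantile-ratio factor

    f_q = p_q(cwv_t) / p_q(cwv),        p_t,q = f_q * p,

where p_q is the binned conditional quartile curve (q = 25, 50, 75).
Aggregation to daily/monthly/annual totals, the wet-day filter
(0.01 mm day⁻¹) and percent reductions live here too.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .empirical import QuantileCurve, lookup_quantile

__all__ = [
    "counterfactual_cwv",
    "quantile_ratio",
    "reduced_precip",
    "aggregate",
    "filter_wet_days",
    "percent_reduction",
    "total_percent_reduction",
    "ReductionSummary",
    "summarize_reductions",
]

logger = logging.getLogger(__name__)

_FREQS = {"daily": "D", "monthly": "MS", "annual": "YS"}
RATIO_EPS = 1e-9  # mm h⁻¹; below this a quartile counts as zero


def counterfactual_cwv(cwv: xr.DataArray, ft: xr.DataArray) -> xr.DataArray:
    """cwv_t[cell, hour] = (1 - f_t[cell, month(hour)]) * cwv[cell, hour].

    ``ft`` must cover every calendar month present in the cwv time axis and
    share the cwv grid exactly.
    """
    months_present = np.unique(cwv["time"].dt.month.values)
    available = set(np.asarray(ft["month"].values).tolist())
    missing = sorted(set(months_present.tolist()) - available)
    if missing:
        raise ValueError(f"transpired fraction undefined for months {missing}")
    for dim in ("lat", "lon"):
        if not np.array_equal(cwv[dim].values, ft[dim].values):
            raise ValueError(f"cwv and ft grids differ along {dim}")
    factor = (1.0 - ft).sel(month=cwv["time"].dt.month)
    factor = factor.drop_vars("month")
    out = (cwv * factor).rename("cwv_t")
    out.attrs = {"units": "mm", "long_name": "column water vapor without Amazon transpiration"}
    return out


def quantile_ratio(
    curve: QuantileCurve,
    cwv,
    cwv_t,
    q: int,
    eps: float = RATIO_EPS,
):
    """Per-hour scaling factor f_q = p_q(cwv_t) / p_q(cwv).

    Conventions: if both quartiles are below ``eps`` the factor is 1 (the
    0/0 case: both states are dry); if only the denominator is below
    ``eps`` the factor is 1 and a warning is logged, since a non-monotone
    curve produced rain from a drier column.  Requires cwv_t <= cwv.
    """
    is_da = isinstance(cwv, xr.DataArray)
    w = np.asarray(cwv.values if is_da else cwv, dtype=float)
    wt = np.asarray(cwv_t.values if isinstance(cwv_t, xr.DataArray) else cwv_t, dtype=float)
    if np.any(wt > w + 1e-9):
        raise ValueError("cwv_t exceeds cwv; transpired fraction must lie in [0, 1]")

    num = lookup_quantile(curve, wt, q)
    den = lookup_quantile(curve, w, q)
    num = np.atleast_1d(np.asarray(num, dtype=float))
    den = np.atleast_1d(np.asarray(den, dtype=float))
    f = np.ones_like(den)
    big = den >= eps
    f[big] = num[big] / den[big]
    anomaly = (~big) & (num >= eps)
    if np.any(anomaly):
        logger.warning(
            "%d hours with p_q(cwv) ~ 0 but p_q(cwv_t) > 0 "
            "(non-monotone curve anomaly); factor set to 1",
            int(anomaly.sum()),
        )
    f = f.reshape(w.shape) if w.shape else float(f[0])
    if is_da:
        return xr.DataArray(f, coords=cwv.coords, dims=cwv.dims, name=f"f_{q}")
    return f


def reduced_precip(
    p,
    curve: QuantileCurve,
    cwv,
    cwv_t,
    q: int,
    eps: float = RATIO_EPS,
):
    """Counterfactual hourly precipitation p_t,q = f_q * p (elementwise).

    Dry hours stay exactly dry.  All inputs must share one shape.
    """
    p_arr = np.asarray(p.values if isinstance(p, xr.DataArray) else p, dtype=float)
    w_arr = np.asarray(cwv.values if isinstance(cwv, xr.DataArray) else cwv, dtype=float)
    if p_arr.shape != w_arr.shape:
        raise ValueError(f"shape mismatch: p {p_arr.shape} vs cwv {w_arr.shape}")
    f = quantile_ratio(curve, cwv, cwv_t, q, eps=eps)
    out = p * f
    if isinstance(out, xr.DataArray):
        out = out.rename(f"p_t_{q}")
        out.attrs = {"units": "mm h-1", "long_name": f"counterfactual precipitation (q={q})"}
    return out


def aggregate(field: xr.DataArray, period: str) -> xr.DataArray:
    """Sum an hourly field to daily/monthly/annual totals (mm per period).

    Incomplete periods (e.g. a partial trailing day) are dropped with a
    warning.  The time coordinate of the result holds period start stamps.
    """
    if period not in _FREQS:
        raise ValueError(f"period must be one of {sorted(_FREQS)}, got {period!r}")
    if "time" not in field.dims or field.sizes["time"] == 0:
        raise ValueError("empty series: nothing to aggregate")
    freq = _FREQS[period]

    time = field.indexes["time"]
    sizes = pd.Series(1, index=time).resample(freq).sum()
    if period == "daily":
        expected = np.full(len(sizes), 24)
    elif period == "monthly":
        expected = np.array([ts.days_in_month * 24 for ts in sizes.index])
    else:
        expected = np.array([(8784 if ts.is_leap_year else 8760) for ts in sizes.index])
    complete = sizes.to_numpy() == expected

    sums = field.resample(time=freq).sum()
    if not complete.all():
        n_drop = int((~complete).sum())
        warnings.warn(
            f"dropping {n_drop} incomplete {period} period(s) from aggregation",
            stacklevel=2,
        )
        sums = sums.isel(time=np.nonzero(complete)[0])
    sums.attrs = {"units": "mm", "long_name": f"{period} precipitation total"}
    return sums


def area_mean(field: xr.DataArray) -> xr.DataArray:
    """Area-wide series: unweighted mean over grid cells."""
    return field.mean(dim=[d for d in ("lat", "lon") if d in field.dims])


def filter_wet_days(daily, cutoff: float = 0.01):
    """Keep days whose total meets or exceeds ``cutoff`` (mm day⁻¹)."""
    if cutoff < 0:
        raise ValueError(f"cutoff must be nonnegative, got {cutoff}")
    if isinstance(daily, xr.DataArray):
        vals = daily.values
    elif isinstance(daily, pd.Series):
        vals = daily.to_numpy()
    else:
        vals = np.asarray(daily, dtype=float)
    if np.any(vals < 0):
        raise ValueError("daily totals must be nonnegative")
    mask = vals >= cutoff
    if isinstance(daily, xr.DataArray):
        return daily.isel(time=np.nonzero(mask)[0]) if daily.ndim == 1 else daily.where(mask)
    if isinstance(daily, pd.Series):
        return daily[mask]
    return vals[mask]


def percent_reduction(observed, counterfactual) -> np.ndarray:
    """Per-period percent reduction 100*(1 - cf/obs) over matched periods.

    Periods with zero observed total are excluded (and logged); an all-zero
    observed series is an error.
    """
    obs = np.asarray(
        observed.values if isinstance(observed, xr.DataArray) else observed, dtype=float
    ).ravel()
    cf = np.asarray(
        counterfactual.values if isinstance(counterfactual, xr.DataArray) else counterfactual,
        dtype=float,
    ).ravel()
    if obs.shape != cf.shape:
        raise ValueError(f"period mismatch: {obs.size} observed vs {cf.size} counterfactual")
    pos = obs > 0
    if not pos.any():
        raise ValueError("all observed totals are zero; percent reduction undefined")
    n_excluded = int((~pos).sum())
    if n_excluded:
        logger.info("excluded %d periods with zero observed total", n_excluded)
    return 100.0 * (1.0 - cf[pos] / obs[pos])


def total_percent_reduction(observed, counterfactual) -> float:
    """Percent reduction of the grand total, 100*(1 - Σcf/Σobs)."""
    obs = float(np.sum(np.asarray(observed)))
    cf = float(np.sum(np.asarray(counterfactual)))
    if obs <= 0:
        raise ValueError("observed total is zero; percent reduction undefined")
    return 100.0 * (1.0 - cf / obs)


@dataclass
class ReductionSummary:
    """Observed vs counterfactual aggregates and reduction statistics.

    Holds per-cell daily/monthly/annual totals for the observed series and
    for each counterfactual quartile series, plus the total cwv reduction.
    Event-size statistics use the area-wide daily series with the wet-day
    filter applied independently to observed and counterfactual series.
    """

    quartiles: tuple[int, ...]
    daily_obs: xr.DataArray
    daily_cf: dict[int, xr.DataArray]
    monthly_obs: xr.DataArray
    monthly_cf: dict[int, xr.DataArray]
    annual_obs: xr.DataArray
    annual_cf: dict[int, xr.DataArray]
    cwv_reduction_pct: float
    wet_day_cutoff: float = 0.01

    # -- event-size statistics (area-wide daily series) ------------------

    def area_daily(self, q: int | None = None) -> xr.DataArray:
        da = self.daily_obs if q is None else self.daily_cf[q]
        return area_mean(da)

    def median_event_mm(self, q: int | None = None) -> float:
        wet = filter_wet_days(self.area_daily(q), self.wet_day_cutoff)
        return float(np.median(wet.values)) if wet.size else float("nan")

    def event_reduction_pct(self, q: int) -> float:
        obs = self.median_event_mm(None)
        cf = self.median_event_mm(q)
        return 100.0 * (1.0 - cf / obs)

    # -- annual / monthly reductions -------------------------------------

    def annual_reduction_cell_years(self, q: int) -> np.ndarray:
        """Percent reduction per (cell, year), zero-observed excluded."""
        return percent_reduction(self.annual_obs, self.annual_cf[q])

    def annual_reduction_pct(self, q: int, stat: str = "median") -> float:
        r = self.annual_reduction_cell_years(q)
        return float(np.median(r) if stat == "median" else np.mean(r))

    def monthly_reduction_table(self, q: int) -> pd.DataFrame:
        """Per-(cell, year-month) reductions with calendar-month labels."""
        obs = self.monthly_obs
        cf = self.monthly_cf[q]
        month = obs["time"].dt.month.values
        month3d = np.broadcast_to(
            month[:, None, None], obs.shape
        ).ravel()
        o = obs.values.ravel()
        c = cf.values.ravel()
        pos = o > 0
        return pd.DataFrame(
            {
                "month": month3d[pos],
                "reduction_pct": 100.0 * (1.0 - c[pos] / o[pos]),
            }
        )

    def monthly_reduction_pct(self, q: int, stat: str = "median") -> float:
        r = self.monthly_reduction_table(q)["reduction_pct"].to_numpy()
        return float(np.median(r) if stat == "median" else np.mean(r))

    # -- per-cell maps ----------------------------------------------------

    def per_cell_annual_reduction_pct(self, q: int) -> xr.DataArray:
        obs = self.annual_obs.sum("time")
        cf = self.annual_cf[q].sum("time")
        out = 100.0 * (1.0 - cf / obs.where(obs > 0))
        out.name = f"annual_reduction_pct_q{q}"
        return out

    def per_cell_annual_decrease_mm(self, q: int) -> xr.DataArray:
        out = (self.annual_obs - self.annual_cf[q]).mean("time")
        out.name = f"annual_decrease_mm_q{q}"
        out.attrs = {"units": "mm year-1"}
        return out

    def total_reduction_pct(self, q: int) -> float:
        return total_percent_reduction(self.annual_obs.values, self.annual_cf[q].values)


def summarize_reductions(
    precip: xr.DataArray,
    precip_cf: dict[int, xr.DataArray],
    cwv: xr.DataArray,
    cwv_t: xr.DataArray,
    wet_day_cutoff: float = 0.01,
) -> ReductionSummary:
    """Aggregate hourly observed/counterfactual fields into a summary."""
    quartiles = tuple(sorted(precip_cf))
    daily_obs = aggregate(precip, "daily")
    monthly_obs = aggregate(precip, "monthly")
    annual_obs = aggregate(precip, "annual")
    daily_cf = {q: aggregate(precip_cf[q], "daily") for q in quartiles}
    monthly_cf = {q: aggregate(precip_cf[q], "monthly") for q in quartiles}
    annual_cf = {q: aggregate(precip_cf[q], "annual") for q in quartiles}
    cwv_red = total_percent_reduction(cwv.values, cwv_t.values)
    return ReductionSummary(
        quartiles=quartiles,
        daily_obs=daily_obs,
        daily_cf=daily_cf,
        monthly_obs=monthly_obs,
        monthly_cf=monthly_cf,
        annual_obs=annual_obs,
        annual_cf=annual_cf,
        cwv_reduction_pct=cwv_red,
        wet_day_cutoff=wet_day_cutoff,
    )
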
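"""Monte Carlo counterfactual: conditional resampling with replacement.

Instead of scaling observed precipitation by a quantile ratio, each hour's
counterfactual precipitation is drawn (with replacement) from the pool of
all observed hourly values at similar column water vapor — "similar"
meaning the same 1-mm bin used throughout the package.  This preserves the
conditional distribution of precipitation but not its temporal structure,
so only daily totals and their distribution are summarized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from .counterfactual import (
    aggregate,
    area_mean,
    filter_wet_days,
    total_percent_reduction,
)

__all__ = ["ConditionalPool", "build_pool", "mc_resample", "mc_daily_summary", "MCSummary"]

_STREAM_MC = 104


@dataclass
class ConditionalPool:
    """Per-bin multisets of observed hourly precipitation values.

    Pools partition the retained observations (cwv in [0, max_cwv)); there
    is no minimum-count rule — empty bins are resolved at sampling time by
    falling back to the nearest non-empty bin at lower cwv.
    """

    bin_lower: np.ndarray
    pools: list[np.ndarray]
    bin_width: float = 1.0
    max_cwv: float = 73.0

    @property
    def n_bins(self) -> int:
        return len(self.pools)

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(p) for p in self.pools])

    def source_bins(self) -> np.ndarray:
        """For each bin, the bin actually sampled from: itself if non-empty,
        else the nearest non-empty bin at lower cwv, else -1 (draw 0)."""
        src = np.full(self.n_bins, -1, dtype=np.intp)
        last = -1
        for i in range(self.n_bins):
            if len(self.pools[i]) > 0:
                last = i
            src[i] = last
        return src


def build_pool(
    cwv,
    p,
    bin_width: float = 1.0,
    max_cwv: float = 73.0,
) -> ConditionalPool:
    """Partition observed (cwv, p) pairs into 1-mm conditional pools."""
    cwv = np.asarray(cwv, dtype=float).ravel()
    p = np.asarray(p, dtype=float).ravel()
    if cwv.size == 0:
        raise ValueError("empty input: no observations to pool")
    if cwv.shape != p.shape:
        raise ValueError("cwv and p must have equal length")
    if not (np.all(np.isfinite(cwv)) and np.all(np.isfinite(p))):
        raise ValueError("cwv and p must be finite")

    n_bins = int(np.ceil(max_cwv / bin_width - 1e-12))
    keep = (cwv >= 0) & (cwv < max_cwv)
    b = np.floor(cwv[keep] / bin_width).astype(np.intp)
    pk = p[keep]
    count = np.bincount(b, minlength=n_bins)
    order = np.argsort(b, kind="stable")
    sorted_p = pk[order]
    starts = np.concatenate([[0], np.cumsum(count)])
    pools = [sorted_p[starts[i]:starts[i + 1]] for i in range(n_bins)]
    return ConditionalPool(
        bin_lower=np.arange(n_bins) * bin_width,
        pools=pools,
        bin_width=bin_width,
        max_cwv=max_cwv,
    )


def _resample_cell(
    wt: np.ndarray,
    flat: np.ndarray,
    offsets: np.ndarray,
    sizes: np.ndarray,
    src: np.ndarray,
    pool: ConditionalPool,
    rng: np.random.Generator,
) -> np.ndarray:
    bins = np.clip(
        np.floor(wt / pool.bin_width).astype(np.intp), 0, pool.n_bins - 1
    )
    s = src[bins]
    out = np.zeros(wt.shape)
    ok = s >= 0
    # One uniform draw per hour regardless of bin, so the stream is stable.
    u = rng.random(wt.size)
    if np.any(ok):
        sz = sizes[s[ok]]
        idx = np.minimum((u[ok] * sz).astype(np.intp), sz - 1)
        out[ok] = flat[offsets[s[ok]] + idx]
    return out


def mc_resample(
    cwv_t: xr.DataArray | np.ndarray,
    pool: ConditionalPool,
    seed: int = 0,
) -> xr.DataArray | np.ndarray:
    """Draw an hourly precipitation field conditional on cwv_t.

    Each hour's value is drawn uniformly with replacement from the pool of
    the 1-mm bin containing that hour's cwv_t (lower-bin fallback for empty
    bins, zero when no lower bin exists).  Each grid cell gets its own
    seeded substream, so per-cell output does not depend on cell order.
    """
    if all(len(p) == 0 for p in pool.pools):
        raise ValueError("conditional pool is empty")
    is_da = isinstance(cwv_t, xr.DataArray)
    wt = np.asarray(cwv_t.values if is_da else cwv_t, dtype=float)

    sizes = pool.counts
    offsets = np.concatenate([[0], np.cumsum(sizes)])[:-1].astype(np.intp)
    flat = np.concatenate(pool.pools) if int(sizes.sum()) else np.zeros(0)
    src = pool.source_bins()

    if wt.ndim == 3:
        out = np.empty_like(wt)
        n_lat, n_lon = wt.shape[1], wt.shape[2]
        for i in range(n_lat):
            for j in range(n_lon):
                rng = np.random.default_rng(
                    np.random.SeedSequence([_STREAM_MC, seed, i * n_lon + j])
                )
                out[:, i, j] = _resample_cell(
                    wt[:, i, j], flat, offsets, sizes, src, pool, rng
                )
    else:
        rng = np.random.default_rng(np.random.SeedSequence([_STREAM_MC, seed, 0]))
        out = _resample_cell(wt.ravel(), flat, offsets, sizes, src, pool, rng).reshape(
            wt.shape
        )

    if is_da:
        return xr.DataArray(
            out,
            coords=cwv_t.coords,
            dims=cwv_t.dims,
            name="precip_mc",
            attrs={"units": "mm h-1", "long_name": "Monte Carlo counterfactual precipitation"},
        )
    return out


@dataclass
class MCSummary:
    """Daily-scale summary of the Monte Carlo counterfactual."""

    daily_obs: xr.DataArray
    daily_mc: xr.DataArray
    median_event_obs_mm: float
    median_event_mc_mm: float
    event_reduction_pct: float
    total_reduction_pct: float
    wet_day_cutoff: float


def mc_daily_summary(
    resampled: xr.DataArray,
    observed: xr.DataArray,
    cutoff: float = 0.01,
) -> MCSummary:
    """Daily totals, wet-day event sizes, and percent reduction.

    Only daily totals and their distribution are reported: the resampled
    series carries no sub-daily temporal structure.
    """
    daily_obs = aggregate(observed, "daily")
    daily_mc = aggregate(resampled, "daily")
    wet_obs = filter_wet_days(area_mean(daily_obs), cutoff)
    wet_mc = filter_wet_days(area_mean(daily_mc), cutoff)
    med_obs = float(np.median(wet_obs.values)) if wet_obs.size else float("nan")
    med_mc = float(np.median(wet_mc.values)) if wet_mc.size else float("nan")
    if med_obs and np.isfinite(med_obs) and med_obs > 0:
        event_red = 100.0 * (1.0 - med_mc / med_obs) if np.isfinite(med_mc) else 100.0
    else:
        event_red = float("nan")
    if float(daily_obs.sum()) > 0:
        total_red = total_percent_reduction(daily_obs.values, daily_mc.values)
    else:
        total_red = float("nan")
    return MCSummary(
        daily_obs=daily_obs,
        daily_mc=daily_mc,
        median_event_obs_mm=med_obs,
        median_event_mc_mm=med_mc,
        event_reduction_pct=event_red,
        total_reduction_pct=total_red,
        wet_day_cutoff=cutoff,
    )
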
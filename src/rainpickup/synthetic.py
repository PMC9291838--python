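"""Synthetic ERA5-like fields for the moisture–precipitation analysis.

Generates, on a regular lat/lon grid:

* hourly column water vapor (cwv, mm) as a seasonal mean plus a clipped
  AR(1) deviation, one independent process per cell;
* hourly precipitation (mm h⁻¹) from a threshold "pickup" law — exactly
  dry below a critical cwv, and above it a superlinear median intensity
  with multiplicative unit-median noise;
* a monthly transpired fraction ``f_t`` of cwv attributable to Amazon tree
  transpiration, with a west-increasing gradient and an optional seasonal
  cycle.

These emulate the statistical structure the counterfactual analysis relies
on (bounded autocorrelated cwv, a sharp precipitation pickup near 60 mm,
mean transpired fraction ≈ 0.13), not any real spatial correlation,
orography or wind field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.signal import lfilter

from .grid import Grid

__all__ = [
    "CwvProcess",
    "PickupLaw",
    "FtParams",
    "simulate_cwv",
    "simulate_precip",
    "simulate_ft",
    "simulate_dataset",
]

# Sub-stream tags so one run seed yields independent streams per field.
_STREAM_CWV = 101
_STREAM_PRECIP = 102
_STREAM_FT = 103


@dataclass
class CwvProcess:
    """Seasonal-mean-plus-AR(1) model for hourly column water vapor.

    ``noise_sd`` is the *stationary* standard deviation of the AR(1)
    deviation; the innovation sd is derived as ``noise_sd*sqrt(1-ar1**2)``.
    Values are clipped to ``clip`` after adding the seasonal mean.
    """

    mean: float = 55.0  # mm
    seasonal_amplitude: float = 8.0  # mm
    seasonal_peak_doy: float = 15.0  # day of year of the cwv maximum (mid-Jan)
    ar1: float = 0.95  # per-hour lag-1 autocorrelation
    noise_sd: float = 5.0  # mm, stationary sd of the AR(1) deviation
    clip: tuple[float, float] = (0.0, 75.0)  # mm

    def validate(self) -> None:
        if not 0.0 <= self.ar1 < 1.0:
            raise ValueError(f"ar1 must be in [0, 1), got {self.ar1}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be nonnegative, got {self.noise_sd}")
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal_amplitude must be nonnegative")
        lo, hi = self.clip
        if not lo < hi:
            raise ValueError(f"clip bounds must satisfy lo < hi, got {self.clip}")


@dataclass
class PickupLaw:
    """Threshold law for precipitation conditional on column water vapor.

    Hours with ``cwv <= w_c`` are exactly dry.  Above the threshold the
    intensity is ``X * a * (cwv - w_c)**beta`` with ``X = exp(sigma(cwv)*Z)``
    a unit-median lognormal factor, so the conditional median is
    ``a * max(0, cwv - w_c)**beta`` in closed form.  The log-scale spread
    ``sigma`` decreases linearly with the excess above the threshold
    (relative spread of convective intensity is largest near onset), which
    makes the lower conditional quartile rise later than the upper one.

    ``wet_prob`` optionally thins above-threshold wet hours; the closed-form
    median contract holds only at the default ``wet_prob = 1``.
    """

    w_c: float = 60.0  # mm, critical cwv
    a: float = 0.06  # mm h⁻¹ per mm**beta; median at 65 mm = 0.06*25 = 1.5
    beta: float = 2.0
    sigma0: float = 1.2  # log-scale noise spread at the threshold
    sigma_decay: float = 0.05  # relative sigma decrease per mm of excess
    sigma_floor: float = 1.0 / 3.0  # floor on sigma as a fraction of sigma0
    wet_prob: float = 1.0

    def validate(self) -> None:
        if self.w_c < 0:
            raise ValueError(f"w_c must be nonnegative, got {self.w_c}")
        if self.a <= 0:
            raise ValueError(f"a must be positive, got {self.a}")
        if self.beta < 1:
            raise ValueError(f"beta must be >= 1, got {self.beta}")
        if self.sigma0 < 0 or self.sigma_decay < 0:
            raise ValueError("noise parameters must be nonnegative")
        if not 0.0 < self.wet_prob <= 1.0:
            raise ValueError(f"wet_prob must be in (0, 1], got {self.wet_prob}")

    def median(self, cwv):
        """Conditional median intensity a*max(0, cwv-w_c)**beta (mm h⁻¹)."""
        excess = np.maximum(0.0, np.asarray(cwv, dtype=float) - self.w_c)
        return self.a * excess**self.beta

    def sigma(self, cwv):
        """Log-scale noise spread at a given cwv."""
        excess = np.maximum(0.0, np.asarray(cwv, dtype=float) - self.w_c)
        return self.sigma0 * np.maximum(
            self.sigma_floor, 1.0 - self.sigma_decay * excess
        )

    def median_ratio(self, cwv, cwv_t):
        """Closed-form f_50 = median(cwv_t)/median(cwv), with 0/0 -> 1."""
        num = self.median(cwv_t)
        den = self.median(cwv)
        out = np.ones(np.broadcast(num, den).shape, dtype=float)
        nz = den > 0
        out[nz] = num[nz] / den[nz]
        return out


@dataclass
class FtParams:
    """Monthly transpired-fraction field parameters.

    ``gradient`` is the total west-minus-east difference in f_t across the
    grid (the fraction increases westward, following the prevailing
    east-to-west moisture transport).  The seasonal term peaks at
    ``seasonal_peak_month`` and averages to zero over the 12 months, so the
    configured ``mean`` is also the area-time mean (before clipping).
    """

    mean: float = 0.13
    gradient: float = 0.08
    seasonal_amplitude: float = 0.02
    seasonal_peak_month: int = 9  # dry-season peak
    noise_sd: float = 0.0

    def validate(self) -> None:
        # mean == 0 is the degenerate no-removal configuration used by
        # end-to-end identity checks; otherwise the mean must be in (0, 1).
        if not 0.0 <= self.mean < 1.0:
            raise ValueError(f"mean transpired fraction must be in [0, 1), got {self.mean}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 1 <= int(self.seasonal_peak_month) <= 12:
            raise ValueError("seasonal_peak_month must be a calendar month 1-12")


def _time_axis(start: str, n_hours: int) -> pd.DatetimeIndex:
    return pd.date_range(start, periods=n_hours, freq="h")


def simulate_cwv(
    grid: Grid,
    n_hours: int,
    process: CwvProcess | None = None,
    seed: int = 0,
    start: str = "2003-01-01",
) -> xr.DataArray:
    """Simulate hourly column water vapor on a grid.

    Returns a DataArray with dims ``(time, lat, lon)``, units mm.
    Reproducible: identical (grid, n_hours, process, seed, start) give
    bit-identical output.
    """
    process = process or CwvProcess()
    process.validate()
    if n_hours < 1:
        raise ValueError(f"n_hours must be >= 1, got {n_hours}")

    time = _time_axis(start, n_hours)
    frac_doy = (time.dayofyear - 1 + time.hour / 24.0).to_numpy(dtype=float)
    seasonal = process.mean + process.seasonal_amplitude * np.cos(
        2.0 * math.pi * (frac_doy - process.seasonal_peak_doy) / 365.25
    )

    shape = (n_hours, grid.n_lat, grid.n_lon)
    if process.noise_sd == 0.0:
        dev = np.zeros(shape)
    else:
        rng = np.random.default_rng(np.random.SeedSequence([_STREAM_CWV, seed]))
        innov_sd = process.noise_sd * math.sqrt(1.0 - process.ar1**2)
        x0 = rng.normal(0.0, process.noise_sd, (grid.n_lat, grid.n_lon))
        eps = rng.normal(0.0, innov_sd, shape)
        # AR(1): dev[t] = ar1*dev[t-1] + eps[t], initialized from the
        # stationary distribution via the filter's initial condition.
        dev, _ = lfilter(
            [1.0], [1.0, -process.ar1], eps, axis=0, zi=(process.ar1 * x0)[None]
        )

    values = np.clip(seasonal[:, None, None] + dev, *process.clip)
    return xr.DataArray(
        values,
        coords={"time": time, "lat": grid.lats, "lon": grid.lons},
        dims=("time", "lat", "lon"),
        name="cwv",
        attrs={"units": "mm", "long_name": "column water vapor"},
    )


def simulate_precip(
    cwv: xr.DataArray | np.ndarray,
    law: PickupLaw | None = None,
    seed: int = 0,
) -> xr.DataArray | np.ndarray:
    """Draw hourly precipitation from the pickup law, conditional on cwv.

    ``p = 0`` wherever ``cwv <= w_c``; above the threshold
    ``p = exp(sigma(cwv)*Z) * a*(cwv-w_c)**beta``.  Returns the same
    container type as the input.
    """
    law = law or PickupLaw()
    law.validate()
    is_da = isinstance(cwv, xr.DataArray)
    w = np.asarray(cwv.values if is_da else cwv, dtype=float)
    if not np.all(np.isfinite(w)) or np.any(w < 0):
        raise ValueError("cwv field must be finite and nonnegative")

    rng = np.random.default_rng(np.random.SeedSequence([_STREAM_PRECIP, seed]))
    p = np.zeros_like(w)
    wet = w > law.w_c
    m = law.a * (w[wet] - law.w_c) ** law.beta
    if law.sigma0 > 0:
        z = rng.standard_normal(m.shape)
        p[wet] = m * np.exp(law.sigma(w[wet]) * z)
    else:
        p[wet] = m
    if law.wet_prob < 1.0:
        p[wet] *= rng.random(m.shape) < law.wet_prob

    if is_da:
        return xr.DataArray(
            p,
            coords=cwv.coords,
            dims=cwv.dims,
            name="precip",
            attrs={"units": "mm h-1", "long_name": "precipitation rate"},
        )
    return p


def simulate_ft(
    grid: Grid,
    params: FtParams | None = None,
    seed: int = 0,
) -> xr.DataArray:
    """Simulate the monthly transpired fraction f_t of column water vapor.

    Returns a DataArray with dims ``(month, lat, lon)`` (month 1..12),
    values in [0, 1].
    """
    params = params or FtParams()
    params.validate()

    months = np.arange(1, 13)
    # Westward-increasing linear gradient, zero-mean across columns.
    if grid.n_lon > 1:
        x = (grid.lons - grid.lons.mean()) / (grid.lons[-1] - grid.lons[0])
    else:
        x = np.zeros(1)
    lon_term = -params.gradient * x  # west (x<0) gets +gradient/2

    seas = params.seasonal_amplitude * np.cos(
        2.0 * math.pi * (months - params.seasonal_peak_month) / 12.0
    )
    values = (
        params.mean
        + seas[:, None, None]
        + np.zeros((12, grid.n_lat, 1))
        + lon_term[None, None, :]
    )
    if params.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([_STREAM_FT, seed]))
        values = values + rng.normal(0.0, params.noise_sd, values.shape)
    values = np.clip(values, 0.0, 1.0)

    return xr.DataArray(
        values,
        coords={"month": months, "lat": grid.lats, "lon": grid.lons},
        dims=("month", "lat", "lon"),
        name="ft",
        attrs={
            "units": "1",
            "long_name": "fraction of column water vapor from Amazon tree transpiration",
        },
    )


def simulate_dataset(
    grid: Grid,
    n_hours: int,
    cwv_process: CwvProcess | None = None,
    pickup: PickupLaw | None = None,
    ft_params: FtParams | None = None,
    seed: int = 0,
    start: str = "2003-01-01",
) -> xr.Dataset:
    """Simulate a full synthetic dataset (cwv, precip, ft) from one seed."""
    cwv = simulate_cwv(grid, n_hours, cwv_process, seed=seed, start=start)
    precip = simulate_precip(cwv, pickup, seed=seed)
    ft = simulate_ft(grid, ft_params, seed=seed)
    return xr.Dataset({"cwv": cwv, "precip": precip, "ft": ft})
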
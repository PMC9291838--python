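"""Empirical precipitation–cwv relation.

The core object is the binned conditional quartile curve: hourly
precipitation quartiles (p_25, p_50, p_75) per 1-mm bin of column water
vapor, a bin being valid only if it holds more than five points, up to a
maximum retained cwv of 73 mm.  All hours enter the curve, including dry
ones — the near-zero medians at low cwv only appear if zeros are kept.

Also provides linear and exponential least-squares fits of p against cwv
(the linearity null-hypothesis test), with R² evaluated on the original,
untransformed scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "QuantileCurve",
    "FitResult",
    "build_quantile_curve",
    "lookup_quantile",
    "fit_linear",
    "fit_exponential",
]

_QUARTILES = (25, 50, 75)


@dataclass
class QuantileCurve:
    """Binned conditional quartiles of precipitation vs column water vapor.

    Bins are left-closed, right-open 1-mm (by default) intervals
    ``[k*w, (k+1)*w)`` from 0 up to ``max_cwv``.  Quartiles use the
    linear-interpolation ("type 7") estimator.  A bin is valid when its
    count is at least ``min_count``; quartiles of empty bins are NaN.
    """

    bin_lower: np.ndarray  # mm
    count: np.ndarray
    p25: np.ndarray  # mm h⁻¹
    p50: np.ndarray
    p75: np.ndarray
    valid: np.ndarray
    bin_width: float = 1.0
    max_cwv: float = 73.0
    min_count: int = 6

    @property
    def n_bins(self) -> int:
        return len(self.bin_lower)

    @property
    def all_invalid(self) -> bool:
        return not bool(np.any(self.valid))

    def values(self, q: int) -> np.ndarray:
        if q not in _QUARTILES:
            raise ValueError(f"q must be one of {_QUARTILES}, got {q}")
        return {25: self.p25, 50: self.p50, 75: self.p75}[q]

    def filled_values(self, q: int) -> np.ndarray:
        """Per-bin lookup table: invalid bins take the nearest valid bin at
        lower cwv, and bins below the lowest valid bin take 0."""
        v = self.values(q)
        out = np.zeros(self.n_bins)
        last = 0.0
        for i in range(self.n_bins):
            if self.valid[i]:
                last = v[i]
            out[i] = last
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lower_mm": self.bin_lower,
                "count": self.count,
                "p25": self.p25,
                "p50": self.p50,
                "p75": self.p75,
                "valid": self.valid.astype(bool),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, bin_width: float | None = None,
                 min_count: int = 6) -> "QuantileCurve":
        df = pd.read_csv(path)
        lower = df["bin_lower_mm"].to_numpy(float)
        if bin_width is None:
            bin_width = float(lower[1] - lower[0]) if len(lower) > 1 else 1.0
        return cls(
            bin_lower=lower,
            count=df["count"].to_numpy(int),
            p25=df["p25"].to_numpy(float),
            p50=df["p50"].to_numpy(float),
            p75=df["p75"].to_numpy(float),
            valid=df["valid"].to_numpy(bool),
            bin_width=bin_width,
            max_cwv=float(lower[-1] + bin_width),
            min_count=min_count,
        )


def build_quantile_curve(
    cwv,
    p,
    bin_width: float = 1.0,
    min_count: int = 6,
    max_cwv: float = 73.0,
) -> QuantileCurve:
    """Bin (cwv, p) pairs along the cwv axis and compute per-bin quartiles.

    Values with ``cwv >= max_cwv`` (or cwv < 0) are excluded.  Bin
    membership is ``floor(cwv / bin_width)``.  Raises ValueError on empty or
    non-finite input; warns if no bin reaches ``min_count``.
    """
    cwv = np.asarray(cwv, dtype=float).ravel()
    p = np.asarray(p, dtype=float).ravel()
    if cwv.size == 0:
        raise ValueError("empty input: no (cwv, p) pairs to bin")
    if cwv.shape != p.shape:
        raise ValueError(f"length mismatch: {cwv.size} cwv vs {p.size} p values")
    if not (np.all(np.isfinite(cwv)) and np.all(np.isfinite(p))):
        raise ValueError("cwv and p must be finite")
    if np.any(p < 0):
        raise ValueError("precipitation values must be nonnegative")
    if bin_width <= 0 or max_cwv <= 0:
        raise ValueError("bin_width and max_cwv must be positive")

    n_bins = int(np.ceil(max_cwv / bin_width - 1e-12))
    keep = (cwv >= 0) & (cwv < max_cwv)
    b = np.floor(cwv[keep] / bin_width).astype(np.intp)
    pk = p[keep]

    count = np.bincount(b, minlength=n_bins)
    p25 = np.full(n_bins, np.nan)
    p50 = np.full(n_bins, np.nan)
    p75 = np.full(n_bins, np.nan)

    order = np.argsort(b, kind="stable")
    sorted_p = pk[order]
    starts = np.concatenate([[0], np.cumsum(count)])
    for i in np.nonzero(count)[0]:
        q = np.quantile(sorted_p[starts[i]:starts[i + 1]], [0.25, 0.5, 0.75])
        p25[i], p50[i], p75[i] = q

    valid = count >= min_count
    curve = QuantileCurve(
        bin_lower=np.arange(n_bins) * bin_width,
        count=count,
        p25=p25,
        p50=p50,
        p75=p75,
        valid=valid,
        bin_width=bin_width,
        max_cwv=max_cwv,
        min_count=min_count,
    )
    if curve.all_invalid:
        warnings.warn(
            f"no cwv bin holds at least {min_count} points; "
            "all bins flagged invalid",
            stacklevel=2,
        )
    return curve


def lookup_quantile(curve: QuantileCurve, cwv, q: int):
    """Piecewise-constant quartile lookup.

    Returns the quartile of the bin containing ``cwv``; invalid bins fall
    back to the nearest valid bin at lower cwv (else 0), and cwv at or above
    the retained range maps to the highest bin's (filled) value.  Accepts
    scalars or arrays.
    """
    if curve.all_invalid:
        raise ValueError("curve has no valid bin")
    filled = curve.filled_values(q)
    arr = np.asarray(cwv, dtype=float)
    idx = np.clip(
        np.floor(arr / curve.bin_width).astype(np.intp), 0, curve.n_bins - 1
    )
    out = filled[idx]
    return float(out) if np.isscalar(cwv) else out


@dataclass
class FitResult:
    """A fitted p(cwv) model with goodness of fit on the original scale."""

    kind: str  # "linear" | "exponential"
    params: dict[str, float]
    r_squared: float

    def predict(self, cwv):
        w = np.asarray(cwv, dtype=float)
        if self.kind == "linear":
            return self.params["slope"] * w + self.params["intercept"]
        return self.params["a"] * np.exp(self.params["b"] * w)


def _r_squared(p, fitted) -> float:
    ss_res = float(np.sum((p - fitted) ** 2))
    ss_tot = float(np.sum((p - p.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else -np.inf
    return 1.0 - ss_res / ss_tot


def _validate_fit_input(cwv, p):
    cwv = np.asarray(cwv, dtype=float).ravel()
    p = np.asarray(p, dtype=float).ravel()
    if cwv.size < 3 or cwv.shape != p.shape:
        raise ValueError("need at least 3 paired (cwv, p) points")
    if np.ptp(cwv) == 0:
        raise ValueError("degenerate input: cwv is constant")
    return cwv, p


def fit_linear(cwv, p) -> FitResult:
    """Ordinary least squares p = slope*cwv + intercept."""
    cwv, p = _validate_fit_input(cwv, p)
    slope, intercept = np.polyfit(cwv, p, 1)
    fitted = slope * cwv + intercept
    return FitResult(
        "linear",
        {"slope": float(slope), "intercept": float(intercept)},
        _r_squared(p, fitted),
    )


def fit_exponential(cwv, p, eps: float = 1e-6) -> FitResult:
    """Nonlinear least squares p = a*exp(b*cwv) on the original scale.

    Initialized from a log-linear fit restricted to wet hours (p > 0);
    initializing on (cwv, p + eps) instead lets the many dry hours drag the
    starting point into a flat region of the loss where the optimizer
    stalls.  The fit itself runs in (log a, b) for numerical stability, and
    the better of initializer and optimizer (by R² on the original scale)
    is reported.
    """
    cwv, p = _validate_fit_input(cwv, p)
    wet = p > 0
    if wet.sum() >= 3 and np.ptp(cwv[wet]) > 0:
        b0, loga0 = np.polyfit(cwv[wet], np.log(p[wet]), 1)
    else:
        b0, loga0 = np.polyfit(cwv, np.log(p + eps), 1)

    def model(w, loga, b):
        return np.exp(np.clip(loga + b * w, -700.0, 700.0))

    try:
        popt, _ = curve_fit(model, cwv, p, p0=[loga0, b0], maxfev=20000)
        loga, b = popt
    except RuntimeError:  # no convergence: report the initializer
        loga, b = loga0, b0
    if _r_squared(p, model(cwv, loga0, b0)) > _r_squared(p, model(cwv, loga, b)):
        loga, b = loga0, b0
    fitted = model(cwv, loga, b)
    return FitResult(
        "exponential",
        {"a": float(np.exp(loga)), "b": float(b)},
        _r_squared(p, fitted),
    )
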
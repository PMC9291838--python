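"""Independent brute-force oracles used to cross-check vectorized code.

Deliberately naive: python loops, explicit sorting, hand-rolled
linear-interpolation quartiles (no numpy.quantile)."""

import math

import numpy as np


def interp_quartile(values, q):
    """Linear interpolation between order statistics ('type 7')."""
    s = sorted(values)
    n = len(s)
    h = (n - 1) * q
    lo = int(math.floor(h))
    frac = h - lo
    if lo + 1 < n:
        return s[lo] + frac * (s[lo + 1] - s[lo])
    return s[lo]


def brute_force_curve(cwv, p, bin_width=1.0, min_count=6, max_cwv=73.0):
    """Sort-and-interpolate reference for the binned quantile curve.

    Returns (count, p25, p50, p75, valid) arrays over bins [0, max_cwv).
    """
    n_bins = int(math.ceil(max_cwv / bin_width - 1e-12))
    bins = {}
    for w, x in zip(cwv, p):
        if 0 <= w < max_cwv:
            bins.setdefault(int(w // bin_width), []).append(x)
    count = np.zeros(n_bins, dtype=int)
    p25 = np.full(n_bins, np.nan)
    p50 = np.full(n_bins, np.nan)
    p75 = np.full(n_bins, np.nan)
    for b, vals in bins.items():
        count[b] = len(vals)
        p25[b] = interp_quartile(vals, 0.25)
        p50[b] = interp_quartile(vals, 0.50)
        p75[b] = interp_quartile(vals, 0.75)
    return count, p25, p50, p75, count >= min_count


def law_implied_bin_median(law, w_in_bin):
    """Median precipitation the pickup law implies for one cwv bin.

    Integrates the lognormal intensity noise over the empirical within-bin
    cwv values: solves F(t) = mean_i Phi((ln t - ln m(w_i)) / sigma(w_i)) = 1/2
    by bisection.  Dry hours (m = 0) contribute a point mass at zero.
    Independent of the binned-quantile code path.
    """
    from scipy.optimize import brentq
    from scipy.stats import norm

    w = np.asarray(w_in_bin, dtype=float)
    m = np.asarray(law.median(w), dtype=float)
    s = np.asarray(law.sigma(w), dtype=float)
    dry = m <= 0
    if dry.mean() >= 0.5:
        return 0.0
    mpos, spos = m[~dry], s[~dry]

    def cdf(log_t):
        wet_cdf = norm.cdf((log_t - np.log(mpos)) / spos).mean()
        return dry.mean() + (1 - dry.mean()) * wet_cdf

    lo = float(np.log(mpos.min()) - 10 * spos.max())
    hi = float(np.log(mpos.max()) + 10 * spos.max())
    return math.exp(brentq(lambda lt: cdf(lt) - 0.5, lo, hi, xtol=1e-12))
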
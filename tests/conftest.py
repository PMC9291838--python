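"""Shared fixtures: a Figure-style worked-example curve and one large
seeded pickup-law run used by the parameter-recovery and cross-method
tests."""

from types import SimpleNamespace

import numpy as np
import pytest

import rainpickup as rp


def make_printed_curve(medians: dict[int, float] | None = None) -> rp.QuantileCurve:
    """A quantile curve holding printed worked-example medians.

    Defaults encode the published illustration: the conditional median is
    0.4 mm/h at 60 mm cwv, 1.5 mm/h at 65 mm, and 10.2 mm/h at 70 mm.
    Quartile bands are synthetic (half/double the median).
    """
    medians = medians or {60: 0.4, 65: 1.5, 70: 10.2}
    n = 73
    count = np.zeros(n, dtype=int)
    p25 = np.full(n, np.nan)
    p50 = np.full(n, np.nan)
    p75 = np.full(n, np.nan)
    for b, med in medians.items():
        count[b] = 100
        p25[b] = med / 2.0
        p50[b] = med
        p75[b] = med * 2.0
    return rp.QuantileCurve(
        bin_lower=np.arange(n, dtype=float),
        count=count,
        p25=p25,
        p50=p50,
        p75=p75,
        valid=count >= 6,
    )


@pytest.fixture
def printed_curve() -> rp.QuantileCurve:
    return make_printed_curve()


@pytest.fixture
def small_grid() -> rp.Grid:
    return rp.make_grid(-4, 0, -65, -61, 1.0)


@pytest.fixture(scope="session")
def pickup_run() -> SimpleNamespace:
    """Two simulated years on an 8x8 grid (~1.1e6 cell-hours) with cwv
    concentrated in 55-72 mm, the default pickup law (w_c=60, beta=2) and a
    uniform transpired fraction of 0.13 — the conditions for the
    parameter-recovery, superlinearity and cross-method checks."""
    grid = rp.make_grid(-8, 0, -65, -57, 1.0)
    process = rp.CwvProcess(
        mean=63.5, seasonal_amplitude=3.5, ar1=0.95, noise_sd=3.5, clip=(55.0, 72.0)
    )
    law = rp.PickupLaw()
    ft_params = rp.FtParams(mean=0.13, gradient=0.0, seasonal_amplitude=0.0)
    ds = rp.simulate_dataset(
        grid, 17544, cwv_process=process, pickup=law, ft_params=ft_params, seed=7
    )
    w = ds["cwv"].values.ravel()
    p = ds["precip"].values.ravel()
    curve = rp.build_quantile_curve(w, p)
    cwv_t = rp.counterfactual_cwv(ds["cwv"], ds["ft"])
    p_t = {
        q: rp.reduced_precip(ds["precip"], curve, ds["cwv"], cwv_t, q)
        for q in (25, 50, 75)
    }
    summary = rp.summarize_reductions(ds["precip"], p_t, ds["cwv"], cwv_t)
    pool = rp.build_pool(w, p)
    resampled = rp.mc_resample(cwv_t, pool, seed=7)
    mc = rp.mc_daily_summary(resampled, ds["precip"])
    return SimpleNamespace(
        grid=grid,
        law=law,
        ft=0.13,
        ds=ds,
        curve=curve,
        cwv_t=cwv_t,
        p_t=p_t,
        summary=summary,
        pool=pool,
        resampled=resampled,
        mc=mc,
    )
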
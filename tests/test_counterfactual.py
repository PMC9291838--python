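import numpy as np
import pandas as pd
import pytest
import xarray as xr

import rainpickup as rp


def hourly_da(values, start="2003-01-01", name="precip"):
    """1-cell hourly DataArray helper."""
    values = np.asarray(values, dtype=float)
    time = pd.date_range(start, periods=len(values), freq="h")
    return xr.DataArray(
        values[:, None, None],
        coords={"time": time, "lat": [0.5], "lon": [0.5]},
        dims=("time", "lat", "lon"),
        name=name,
        attrs={"units": "mm h-1"},
    )


def ft_da(value, grid=None):
    lat = [0.5] if grid is None else grid.lats
    lon = [0.5] if grid is None else grid.lons
    return xr.DataArray(
        np.full((12, len(lat), len(lon)), float(value)),
        coords={"month": np.arange(1, 13), "lat": lat, "lon": lon},
        dims=("month", "lat", "lon"),
        name="ft",
    )


class TestCounterfactualCwv:
    def test_zero_fraction_is_identity(self):
        cwv = hourly_da(np.full(48, 70.0), name="cwv")
        out = rp.counterfactual_cwv(cwv, ft_da(0.0))
        assert np.array_equal(out.values, cwv.values)

    def test_full_fraction_removes_everything(self):
        cwv = hourly_da(np.full(48, 70.0), name="cwv")
        out = rp.counterfactual_cwv(cwv, ft_da(1.0))
        assert np.all(out.values == 0.0)

    def test_arithmetic(self):
        cwv = hourly_da([70.0], name="cwv")
        out = rp.counterfactual_cwv(cwv, ft_da(0.13))
        assert out.values.ravel()[0] == pytest.approx(70.0 * 0.87)  # 60.9 mm

    def test_missing_month_error_lists_keys(self):
        cwv = hourly_da(np.full(24, 70.0), start="2003-05-01", name="cwv")
        ft = ft_da(0.13).sel(month=[1, 2, 3])
        with pytest.raises(ValueError, match=r"\[5\]"):
            rp.counterfactual_cwv(cwv, ft)

    def test_monthly_fraction_applied_by_calendar_month(self):
        # two months, different fractions
        n = (31 + 28) * 24
        cwv = hourly_da(np.full(n, 60.0), name="cwv")
        ft = ft_da(0.0)
        ft.loc[{"month": 2}] = 0.5
        out = rp.counterfactual_cwv(cwv, ft)
        jan = out.sel(time=out["time"].dt.month == 1)
        feb = out.sel(time=out["time"].dt.month == 2)
        assert np.all(jan.values == 60.0) and np.all(feb.values == 30.0)


class TestQuantileRatio:
    def test_unchanged_cwv_gives_unit_factor(self, printed_curve):
        for q in (25, 50, 75):
            assert rp.quantile_ratio(printed_curve, 65.0, 65.0, q) == 1.0

    def test_printed_median_ratio(self, printed_curve):
        f = rp.quantile_ratio(printed_curve, 65.0, 60.0, 50)
        assert f == pytest.approx(0.4 / 1.5)

    def test_both_dry_gives_unit_factor(self, printed_curve):
        assert rp.quantile_ratio(printed_curve, 20.0, 10.0, 50) == 1.0

    def test_moistening_rejected(self, printed_curve):
        with pytest.raises(ValueError):
            rp.quantile_ratio(printed_curve, 60.0, 65.0, 50)


class TestReducedPrecip:
    def test_direct_product(self, printed_curve):
        # f_50(65 -> 60) = 0.4/1.5; p = 2.0
        out = rp.reduced_precip(
            np.array([2.0]), printed_curve, np.array([65.0]), np.array([60.0]), 50
        )
        assert out[0] == pytest.approx(2.0 * 0.4 / 1.5)

    def test_dry_hours_stay_dry(self, printed_curve):
        out = rp.reduced_precip(
            np.zeros(5), printed_curve, np.full(5, 65.0), np.full(5, 60.0), 50
        )
        assert np.all(out == 0.0)

    def test_shape_mismatch_rejected(self, printed_curve):
        with pytest.raises(ValueError, match="shape"):
            rp.reduced_precip(
                np.zeros(4), printed_curve, np.full(5, 65.0), np.full(5, 60.0), 50
            )


class TestAggregate:
    def test_daily_sum(self):
        da = hourly_da(np.full(24, 0.1))
        out = rp.aggregate(da, "daily")
        assert out.shape[0] == 1
        assert float(out.sum()) == pytest.approx(2.4)

    def test_all_zero_hours_give_zero_totals(self):
        out = rp.aggregate(hourly_da(np.zeros(48)), "daily")
        assert np.all(out.values == 0.0)

    def test_two_days_match_brute_force(self):
        rng = np.random.default_rng(0)
        vals = rng.random(48)
        out = rp.aggregate(hourly_da(vals), "daily")
        assert out.values.ravel() == pytest.approx(
            [vals[:24].sum(), vals[24:].sum()]
        )

    def test_partial_trailing_day_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="incomplete"):
            out = rp.aggregate(hourly_da(np.ones(30)), "daily")
        assert out.shape[0] == 1 and float(out.sum()) == 24.0

    def test_monthly_and_annual_totals(self):
        n = 365 * 24
        da = hourly_da(np.ones(n))  # 2003 is not a leap year
        monthly = rp.aggregate(da, "monthly")
        annual = rp.aggregate(da, "annual")
        assert monthly.shape[0] == 12
        assert float(monthly.isel(time=0).sum()) == 31 * 24
        assert annual.shape[0] == 1 and float(annual.sum()) == n

    def test_empty_series_rejected(self):
        da = hourly_da(np.ones(5)).isel(time=[])
        with pytest.raises(ValueError, match="empty"):
            rp.aggregate(da, "daily")

    def test_unknown_period_rejected(self):
        with pytest.raises(ValueError):
            rp.aggregate(hourly_da(np.ones(24)), "weekly")


class TestWetDayFilter:
    def test_cutoff_convention(self):
        kept = rp.filter_wet_days(np.array([0.005, 0.01, 0.0, 0.02]))
        assert kept.tolist() == [0.01, 0.02]

    def test_toy_series_retains_two_days(self):
        assert len(rp.filter_wet_days(np.array([0.0, 0.02, 0.005, 3.1]))) == 2

    def test_negative_cutoff_rejected(self):
        with pytest.raises(ValueError):
            rp.filter_wet_days(np.array([1.0]), cutoff=-0.01)

    def test_negative_totals_rejected(self):
        with pytest.raises(ValueError):
            rp.filter_wet_days(np.array([-1.0]))


class TestPercentReduction:
    def test_equal_series_zero_percent(self):
        out = rp.percent_reduction(np.array([2.0, 3.0]), np.array([2.0, 3.0]))
        assert np.allclose(out, 0.0)

    def test_printed_event_size_arithmetic(self):
        assert rp.percent_reduction(np.array([4.30]), np.array([1.37]))[
            0
        ] == pytest.approx(68.1, abs=0.05)
        assert rp.percent_reduction(np.array([4.30]), np.array([1.41]))[
            0
        ] == pytest.approx(67.2, abs=0.05)

    def test_zero_observed_periods_excluded(self):
        out = rp.percent_reduction(np.array([0.0, 4.0]), np.array([0.0, 1.0]))
        assert out.tolist() == [75.0]

    def test_all_zero_observed_rejected(self):
        with pytest.raises(ValueError):
            rp.percent_reduction(np.zeros(3), np.zeros(3))


class TestPipelineProperties:
    def test_zero_fraction_end_to_end_identity(self, small_grid):
        """With no transpired moisture removed, p_t,q == p exactly."""
        ds = rp.simulate_dataset(
            small_grid,
            24 * 60,
            cwv_process=rp.CwvProcess(mean=63.0, seasonal_amplitude=2.0),
            ft_params=rp.FtParams(mean=0.0, gradient=0.0, seasonal_amplitude=0.0),
            seed=9,
        )
        curve = rp.build_quantile_curve(
            ds["cwv"].values.ravel(), ds["precip"].values.ravel()
        )
        cwv_t = rp.counterfactual_cwv(ds["cwv"], ds["ft"])
        for q in (25, 50, 75):
            p_t = rp.reduced_precip(ds["precip"], curve, ds["cwv"], cwv_t, q)
            assert np.array_equal(p_t.values, ds["precip"].values)

    def test_hourly_f50_matches_generating_law(self, pickup_run):
        """Quantile-ratio factors recover ((cwv_t-w_c)/(cwv-w_c))^beta."""
        law = pickup_run.law
        w = pickup_run.ds["cwv"].values.ravel()
        wt = pickup_run.cwv_t.values.ravel()
        f50 = rp.quantile_ratio(pickup_run.curve, w, wt, 50)
        counts = pickup_run.curve.count
        # hours whose cwv and cwv_t bins are both well populated and whose
        # counterfactual column still exceeds the threshold by >= 1 mm
        bo = np.floor(w).astype(int)
        bt = np.floor(wt).astype(int)
        sel = (
            (wt >= law.w_c + 1.0)
            & (counts[np.clip(bo, 0, 72)] >= 1000)
            & (counts[np.clip(bt, 0, 72)] >= 1000)
            & (w < 73)
        )
        assert sel.sum() > 1000
        expected = law.median_ratio(w[sel], wt[sel])
        # binning discretizes both curve lookups; the bulk of hours must
        # still track the closed form closely
        rel = np.abs(f50[sel] - expected) / expected
        assert np.median(rel) < 0.15

    def test_reduction_ordering_across_quartiles(self, pickup_run):
        """Lower-quartile scaling removes most: r_25 >= r_50 >= r_75."""
        s = pickup_run.summary
        r = {q: s.annual_reduction_pct(q, "mean") for q in (25, 50, 75)}
        assert r[25] >= r[50] >= r[75]

    def test_monotone_curve_bounds_reductions(self, pickup_run):
        """With a nondecreasing curve, factors and reductions are in range."""
        c = pickup_run.curve
        v = c.p50[c.valid]
        assert np.all(np.diff(v) >= -1e-9)  # monotone median curve
        for q in (25, 50, 75):
            r = pickup_run.summary.annual_reduction_cell_years(q)
            assert np.all(r >= 0.0) and np.all(r <= 100.0)

    def test_counterfactual_never_exceeds_observed(self, pickup_run):
        for q in (25, 50, 75):
            assert float(pickup_run.p_t[q].sum()) <= float(
                pickup_run.ds["precip"].sum()
            )
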
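"""End-to-end orchestration: simulate → fit relation → counterfactual →
Monte Carlo → diagnostics, with a machine-readable run report.

The report contains every analysis constant in effect plus the headline
outputs (mean transpired fraction, cwv reduction, percent precipitation
reductions per method and quartile).  Identical configs and seeds yield
byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import xarray as xr

from . import __version__
from .config import RunConfig
from .counterfactual import (
    counterfactual_cwv,
    reduced_precip,
    summarize_reductions,
)
from .diagnostics import (
    mean_transpired_fraction,
    seasonal_cycle,
    spatial_profile,
)
from .empirical import build_quantile_curve, fit_exponential, fit_linear
from .io import write_gridded
from .montecarlo import build_pool, mc_daily_summary, mc_resample
from .synthetic import simulate_dataset

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage of the pipeline failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage-tagged rethrow
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("simulate")
def _simulate(config: RunConfig) -> xr.Dataset:
    grid = config.grid.build()
    return simulate_dataset(
        grid,
        config.n_hours,
        cwv_process=config.cwv,
        pickup=config.pickup,
        ft_params=config.ft,
        seed=config.seed,
        start=config.start,
    )


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run the full analysis; return (and optionally write) the report."""
    a = config.analysis
    logger.info(
        "analysis constants: bin_width=%s mm, min_count=%s, max_cwv=%s mm, "
        "wet_day_cutoff=%s mm/day, ratio_eps=%s mm/h",
        a.bin_width, a.min_count, a.max_cwv, a.wet_day_cutoff, a.ratio_eps,
    )

    ds = _simulate(config)
    cwv, precip, ft = ds["cwv"], ds["precip"], ds["ft"]

    @_stage("fit-relation")
    def fit_relation():
        w = cwv.values.ravel()
        p = precip.values.ravel()
        curve = build_quantile_curve(
            w, p, bin_width=a.bin_width, min_count=a.min_count, max_cwv=a.max_cwv
        )
        return curve, fit_linear(w, p), fit_exponential(w, p)

    curve, lin, expo = fit_relation()

    @_stage("counterfactual")
    def counterfactual():
        cwv_t = counterfactual_cwv(cwv, ft)
        p_t = {
            q: reduced_precip(precip, curve, cwv, cwv_t, q, eps=a.ratio_eps)
            for q in a.quartiles
        }
        summary = summarize_reductions(
            precip, p_t, cwv, cwv_t, wet_day_cutoff=a.wet_day_cutoff
        )
        return cwv_t, p_t, summary

    cwv_t, p_t, summary = counterfactual()

    @_stage("montecarlo")
    def montecarlo():
        pool = build_pool(
            cwv.values.ravel(), precip.values.ravel(),
            bin_width=a.bin_width, max_cwv=a.max_cwv,
        )
        resampled = mc_resample(cwv_t, pool, seed=config.seed)
        return resampled, mc_daily_summary(resampled, precip, cutoff=a.wet_day_cutoff)

    resampled, mc = montecarlo()

    @_stage("report")
    def report():
        seasonal = seasonal_cycle(summary)
        lon_profile = spatial_profile(summary, "longitude")
        lat_profile = spatial_profile(summary, "latitude")
        rep = {
            "version": __version__,
            "config": config.to_dict(),
            "constants": {
                "bin_width_mm": a.bin_width,
                "min_count": a.min_count,
                "max_cwv_mm": a.max_cwv,
                "wet_day_cutoff_mm_day": a.wet_day_cutoff,
                "ratio_eps_mm_h": a.ratio_eps,
            },
            "fits": {
                "linear_r2": lin.r_squared,
                "exponential_r2": expo.r_squared,
                "linear_params": lin.params,
                "exponential_params": expo.params,
            },
            "mean_transpired_fraction_pct": mean_transpired_fraction(ft),
            "cwv_reduction_pct": summary.cwv_reduction_pct,
            "quantile_method": {
                str(q): {
                    "annual_reduction_pct_median": summary.annual_reduction_pct(q, "median"),
                    "annual_reduction_pct_mean": summary.annual_reduction_pct(q, "mean"),
                    "monthly_reduction_pct_median": summary.monthly_reduction_pct(q),
                    "total_reduction_pct": summary.total_reduction_pct(q),
                    "median_event_mm_day": summary.median_event_mm(q),
                    "event_reduction_pct": summary.event_reduction_pct(q),
                }
                for q in a.quartiles
            },
            "median_event_obs_mm_day": summary.median_event_mm(None),
            "monte_carlo": {
                "median_event_mm_day": mc.median_event_mc_mm,
                "event_reduction_pct": mc.event_reduction_pct,
                "total_reduction_pct": mc.total_reduction_pct,
            },
            "seasonal_profile": seasonal.to_frame().to_dict(orient="list"),
            "longitude_profile": lon_profile.to_frame().to_dict(orient="list"),
            "latitude_profile": lat_profile.to_frame().to_dict(orient="list"),
        }
        return rep, seasonal, lon_profile, lat_profile

    rep, seasonal, lon_profile, lat_profile = report()

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gridded(ds, outdir / "fields.nc")
        write_gridded(cwv_t, outdir / "cwvt.nc")
        for q, da in p_t.items():
            write_gridded(da, outdir / f"pt_q{q}.nc")
        write_gridded(resampled, outdir / "precip_mc.nc")
        for period in ("daily", "monthly", "annual"):
            agg = getattr(summary, f"{period}_obs")
            agg_ds = xr.Dataset({"obs": agg})
            for q in a.quartiles:
                agg_ds[f"q{q}"] = getattr(summary, f"{period}_cf")[q]
            for var in agg_ds.data_vars.values():
                var.attrs.setdefault("units", "mm")
            write_gridded(agg_ds, outdir / f"totals_{period}.nc")
        curve.to_csv(outdir / "quantile_curve.csv")
        seasonal.to_frame().to_csv(outdir / "seasonal_profile.csv", index=False)
        lon_profile.to_frame().to_csv(outdir / "longitude_profile.csv", index=False)
        lat_profile.to_frame().to_csv(outdir / "latitude_profile.csv", index=False)
        config.to_yaml(outdir / "config.yml")
        with open(outdir / "report.json", "w") as fh:
            json.dump(rep, fh, indent=2, sort_keys=True)
        manifest = sorted(p.name for p in outdir.iterdir())
        with open(outdir / "manifest.txt", "w") as fh:
            fh.write("\n".join(m for m in manifest if m != "manifest.txt") + "\n")

    return rep
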
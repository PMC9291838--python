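# rainpickup

Counterfactual precipitation analysis built on the *pickup relation* — the
sharply nonlinear dependence of hourly precipitation on column water vapor
(cwv) that marks the onset of deep tropical convection. The package asks:
if the moisture that Amazon trees transpire into the atmosphere were
removed, how much precipitation would be lost? Because precipitation is
negligible below a critical cwv near 60 mm and rises steeply above it, a
modest fractional loss of column moisture can erase a disproportionately
large fraction of rainfall — the central quantity here is exactly that
amplification.

It is aimed at land–atmosphere interaction and moisture-recycling
researchers who have (i) hourly gridded cwv and precipitation (ERA5-style
reanalysis) and (ii) monthly per-cell estimates `f_t` of the fraction of
column water vapor attributable to upwind tree transpiration, from a
moisture-tracking model. A synthetic generator with the same statistical
structure is included, so the full pipeline runs and is tested end to end
without any external data.

## Method

1. **Empirical relation.** Pool all hourly (cwv, p) pairs over the study
   area and bin them every mm of cwv. Per bin, compute the conditional
   quartiles p_q (q = 25, 50, 75%), keeping a bin only if it holds more
   than five points, up to a maximum retained cwv of 73 mm. Linear and
   exponential fits of p(cwv) quantify how poorly a straight line does.
2. **Counterfactual moisture.** cwv_t = (1 − f_t) · cwv, applying each
   calendar month's transpired fraction to all hours of that month.
3. **Quantile-ratio scaling.** Each hour's precipitation is scaled by
   f_q = p_q(cwv_t) / p_q(cwv), giving p_t,q = f_q · p for each quartile.
   Daily, monthly and annual totals of p and p_t,q yield percent
   reductions; daily event-size statistics use wet days only
   (total ≥ 0.01 mm day⁻¹).
4. **Monte Carlo alternative.** Instead of scaling, draw each hour's
   counterfactual precipitation with replacement from all observed values
   in the 1-mm bin containing cwv_t. This preserves the conditional
   distribution (but not temporal structure), so only daily totals are
   summarized.
5. **Diagnostics.** Seasonal cycle of the reduction, longitudinal and
   latitudinal profiles, mean transpired fraction, and a post-rain-event
   cwv-change check.

## Worked example

```python
from rainpickup import RunConfig, GridConfig, CwvProcess, run_pipeline

config = RunConfig(
    grid=GridConfig(south=-2, north=0, west=-65, east=-63, resolution=1.0),
    n_hours=24 * 365,
    cwv=CwvProcess(mean=63.0, seasonal_amplitude=2.0, noise_sd=3.0),
    seed=5,
)
rep = run_pipeline(config)
print(f"mean transpired fraction: {rep['mean_transpired_fraction_pct']:.1f}%")
print(f"cwv reduction:            {rep['cwv_reduction_pct']:.1f}%")
q50 = rep["quantile_method"]["50"]
print(f"annual precip reduction:  {q50['annual_reduction_pct_median']:.1f}%"
      " (median over cell-years, q=50)")
```

prints

```
mean transpired fraction: 13.0%
cwv reduction:            13.0%
annual precip reduction:  98.0% (median over cell-years, q=50)
```

A 13% loss of column moisture removes almost all precipitation in this
synthetic climate: the simulated cwv sits close to the 60-mm pickup
threshold, so scaling cwv down by 0.87 pushes most hours below the point
where rain occurs at all. The amplification (here ×7.5) is the qualitative
signature the method is built to expose; its magnitude depends on where the
cwv distribution sits relative to the threshold. The same run reports the
Monte Carlo method's reduction (within a couple of points of the
quantile-ratio result) and the fit comparison (exponential R² above linear
R²).

The same analysis is scriptable stage by stage from a shell:

```sh
rainpickup simulate --config run.yml --seed 1 --out fields.nc
rainpickup fit-relation --in fields.nc --out curve.csv
rainpickup counterfactual --cwv fields.nc --precip fields.nc \
    --ft fields.nc --curve curve.csv --out out/
rainpickup montecarlo --cwv fields.nc --precip fields.nc --ft fields.nc \
    --seed 1 --out out/
rainpickup report --summary out/ --out out/
# or everything at once:
rainpickup run-all --config run.yml --seed 1 --out out/
```

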
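# Methods

## The counterfactual model

The analysis estimates precipitation in the absence of Amazon
tree-transpired moisture without rerunning any atmospheric model. Its core
assumption is that the empirical conditional relation between hourly
precipitation p and column water vapor cwv — the pickup relation — would
continue to hold at the lower moisture levels of the counterfactual
atmosphere. Removing transpired moisture moves each hour leftward along
that curve:

* cwv_t = (1 − f_t) · cwv, with f_t the monthly per-cell transpired
  fraction applied uniformly to every hour of the calendar month;
* p_t,q = f_q · p with f_q = p_q(cwv_t) / p_q(cwv), the ratio of the
  binned conditional quartile evaluated at the counterfactual and observed
  moisture levels.

What the model deliberately ignores: circulation and wind-field feedbacks,
temperature dependence of the moisture–precipitation relation, orography,
and the post-rain depletion of cwv in the counterfactual series (the
diagnostic below checks how large that last effect is in a given dataset).
Percent reductions are therefore conditional statements about the observed
sequence of atmospheric states, not a climate simulation.

Because f_q is a ratio of quartiles of the *same* empirical curve, the
method is exact under the null (f_t ≡ 0 reproduces p bit for bit) and,
whenever the curve is nondecreasing in cwv, bounded: 0 ≤ f_q ≤ 1 and all
reductions lie in [0, 100]%.

## The empirical quantile curve

* Bins are left-closed 1-mm intervals indexed by floor(cwv); data at
  cwv ≥ 73 mm are discarded (sparse extreme bins), and a bin is valid only
  with at least 6 points.
* All hours enter the curve, dry ones included — the near-zero medians
  below the pickup threshold exist only because dry hours are counted.
* Quartiles use linear interpolation between order statistics (the common
  "type 7" estimator), chosen as the most widespread reproducible default.
* Lookup is piecewise constant. Invalid bins fall back to the nearest
  valid bin at lower cwv (0 if none), and cwv beyond the retained range
  clamps to the highest bin. The lower-side fallback never inflates
  precipitation, matching the monotone character of the relation.
* Ratio conventions: both quartiles below ε = 10⁻⁹ mm h⁻¹ → f_q = 1 (both
  states dry); denominator alone below ε → f_q = 1 with a logged warning,
  since that indicates a non-monotone anomaly in the curve.
* The relation is pooled area-wide (one curve for the study box), the
  granularity at which the analysis is defined; nothing prevents building
  per-cell curves by calling `build_quantile_curve` on a single cell's
  series.

The linear/exponential comparison fits p = β₀ + β₁·cwv and p = a·e^(b·cwv)
by least squares on the original scale and reports R² = 1 − SS_res/SS_tot,
also on the original scale. The exponential fit is initialized from a
log-linear fit on wet hours only: an initializer using log(p + ε) over all
hours is dominated by the dry majority and starts the optimizer in a flat
region of the loss where it stalls. The optimizer works in (log a, b); if
it fails to improve on the initializer, the initializer is reported.

## Monte Carlo resampling

For each hour, a counterfactual precipitation value is drawn uniformly
with replacement from the pool of all observed values in the 1-mm bin
containing cwv_t (the same binning as the curve; no minimum-count rule).
Empty bins fall back to the nearest non-empty bin at lower cwv, else 0.
Each grid cell draws from its own seeded substream
(`SeedSequence([stream, seed, cell_index])`), so per-cell output is
independent of grid shape and iteration order; one uniform variate is
consumed per hour regardless of bin, keeping streams aligned across pool
layouts. The method preserves the conditional distribution of
precipitation but destroys temporal autocorrelation, so only daily totals
and their distribution are reported from it.

## Synthetic data generator

The generator emulates the statistical structure the analysis relies on,
not Amazonian meteorology:

* **cwv**: per-cell seasonal mean plus AR(1) deviation,
  `mean + A·cos(2π(doy − peak)/365.25) + dev`, clipped to [0, 75] mm.
  Defaults: mean 55 mm, amplitude 8 mm (peak mid-January), lag-1
  autocorrelation 0.95 h⁻¹, stationary deviation sd 5 mm. `noise_sd` is
  the stationary sd; the innovation sd is derived as
  `noise_sd·sqrt(1 − ar1²)`.
* **precipitation**: exactly dry at cwv ≤ w_c; above the threshold,
  p = X · a·(cwv − w_c)^β with X = exp(σ(cwv)·Z) a unit-median lognormal
  factor. Defaults w_c = 60 mm, β = 2, a = 0.06 mm h⁻¹ mm⁻² (so the median
  at 65 mm is 1.5 mm h⁻¹). The closed-form conditional median
  a·(cwv − w_c)^β is what the recovery tests check against. The log-spread
  σ decreases linearly from 1.2 at the threshold (floor at a third of
  that): relative intensity spread is largest near convective onset. This
  also gives the quartile curves genuinely different shapes, so the
  reduction ordering across quartiles (q=25 scaling removes most, q=75
  least) is a property of the generated data rather than an artifact.
* **f_t**: per calendar month (12 values per cell), mean 0.13, a linear
  west-minus-east gradient of 0.08 (moisture arrives from the east, so the
  transpired share grows downwind), a small seasonal cosine (amplitude
  0.02, peaking in September), optional Gaussian noise (default off),
  clipped to [0, 1]. A configured mean of exactly 0 is accepted as the
  degenerate no-removal field used by identity checks.

Not emulated: spatial correlation of weather between cells, wind fields,
orography, and the feedback of rain on subsequent cwv. Passing tests on
synthetic data therefore validate the *estimator machinery* — binning,
scaling, resampling, aggregation — and its closed-form recovery, not any
claim about the real Amazon.

## Problem sizes and numerical choices

* Default run configuration: the 0–18°S, 65–50°W study box at 0.75°
  (480 cells) for two simulated years (17 544 h), ≈ 8.4 million
  cell-hours — enough that every populated 1-mm bin above the threshold
  holds thousands of points, while a full pipeline run completes in well
  under a minute. The statistical test fixture uses an 8×8 grid for two
  years (≈ 1.1 million cell-hours) with cwv concentrated in 55–72 mm and a
  uniform f_t = 0.13.
* Aggregation drops incomplete calendar periods with a warning; area-wide
  series are unweighted cell means (the study box is small enough that
  cos-latitude weights change nothing of substance).
* Periods with zero observed precipitation are excluded from percent-
  reduction statistics (and counted in the log) to avoid 0/0.
* The wet-day filter (≥ 0.01 mm day⁻¹) is applied independently to the
  observed and counterfactual daily series before event-size medians; the
  alternative — a common day set — is a one-line change but is not the
  literal reading of removing dry days "from those results".
* Annual percent reduction is computed per cell-year as 100·(1 − Σp_t/Σp)
  and summarized by both median and mean across cell-years; monthly
  reduction analogously per (cell, year-month), pooled by calendar month
  for the seasonal profile. The seasonal band comes from the q=25 (upper
  edge, largest reduction) and q=75 (lower edge) series.
* Post-event cwv diagnostic: event onsets are hours with p ≥ 1 mm h⁻¹ and
  no exceedance in the preceding 6 h; Δcwv is the mean over the 3 h after
  minus the 3 h before, pooled over cells, summarized by the mean with a
  seeded bootstrap 95% interval. These defaults are configurable and are a
  declared approximation of an event-based check, validated by injected-
  effect recovery rather than against any published procedure.
* Reproducibility: every stochastic component draws from
  `numpy.random.default_rng(SeedSequence([stream_tag, seed, ...]))` with
  fixed per-field stream tags, so a single run seed yields independent,
  bit-reproducible streams for cwv, precipitation, f_t, resampling and
  bootstrap.

## Known limitations

* The quantile-ratio method scales each hour independently; multi-hour
  storm structure is preserved in timing but not re-derived from the
  counterfactual moisture field.
* Piecewise-constant quartile lookup discretizes cwv at 1 mm. Near the
  threshold the law varies several-fold within one bin, so hourly scaling
  factors there carry O(10–40%) discretization error even when the curve
  itself is accurate; aggregate reductions are much less sensitive.
* With all mass of the cwv distribution near or above the threshold, the
  counterfactual reduction saturates toward 100%; the amplification factor
  is meaningful, its absolute value is distribution-dependent.
* The Monte Carlo estimator inherits sampling noise in thin bins; its
  lower-bin fallback is conservative (never wetter than observed
  conditions at comparable moisture).
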
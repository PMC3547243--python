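# Methods

## Season delimitation

A percentage method delimits the pollen season as the span holding a
central fraction of the annual pollen sum. We define the start as the
*first* day whose cumulative sum reaches the start fraction and the
end as the *first* day whose cumulative sum reaches the end fraction,
with ">=" attainment. Two consequences drove this choice: a
point-mass year (all pollen on one day) yields a well-defined
one-day season under every method, and a season can never end on a
zero-concentration day after the mass has already been reached. An
alternative convention defines the end as the *last* day below the
upper fraction; the two differ only across runs of zero days and the
first-attainment rule is the conservative one. Cumulative fractions
are computed over the full calendar year; a trimmed window (to ignore
stray autumn grains) can be emulated by zeroing days upstream.

Missing monitoring days are treated as zero for cumulation, with a
logged warning; a strict mode raises instead. The peak is searched
within the delimited season by default, with earliest-day
tie-breaking, so the peak day is method-independent whenever the peak
lies inside every method's season.

The seasonal pollen index (SPI) is the concentration sum over the
delimited season, so SPI(90 %) <= SPI(95 %) <= SPI(98 %) <= annual
total by construction. Inter-annual variability of each
characteristic is compared by the coefficient of variation
V % = 100 * SD / mean with the sample (n-1) SD.

## Meteorological features

Daily indicators follow Polish climatological-station practice: mean
daily temperature (t_max + t_min + t_7 + t_19)/4; mean relative
humidity (2 f_7 + f_13 + f_19)/4 (the morning reading weighs double);
cloudiness as the mean of the 6/12/18 UTC observations on the 0-10
scale rescaled to percent; relative sunshine as sunshine hours over
astronomical day length. Trace rainfall (the 0.01 mm sentinel)
participates in means as 0.01; a switch zeroes it.

Windows are fixed day-of-year decades (decade k = days 10(k-1)+1 to
10k; days 361 onward form a short final block excluded from decade
features), explicit day ranges, or calendar-month sets. Decade
indexing is ordinal from 1 January, so leap years shift which dates
fall in later decades but not the day numbers themselves. Multi-month
features average *daily* values over the concatenated span rather
than taking a mean of monthly means; with unequal month lengths the
two differ, and the daily basis is the literal reading of "mean
March-April daily temperature". Decade rainfall features default to
the mean of daily totals (matching the "mean daily rainfall" label);
a sum statistic is available per window.

A window tolerates up to 20 % missing days (mean over the available
days); beyond that the feature is unavailable (NaN) for that year,
never zero. The threshold is a completeness compromise: strict
no-missing rules would discard whole years for single gaps, while
unbounded tolerance would let two observations represent a decade.

## Screening and model building

Every feature/characteristic pair is tested by Spearman rank
correlation with average ranks on ties; the two-tailed p value uses
the t approximation with n-2 degrees of freedom, the behaviour of the
desktop statistics packages this workflow historically ran on. An
exact permutation mode exists for n <= 10. No multiple-testing
correction is applied — the screen mirrors the per-pair 0.01
convention of the field's correlation tables — but the number of
tests performed is attached to the result so the family-wise risk is
visible. Years missing either member of a pair are dropped pairwise.

Model candidates are first filtered for mutual collinearity: features
are visited in decreasing absolute marginal correlation with the
target and retained only if their absolute pairwise correlation with
every already-retained feature is <= 0.7. The threshold reflects how
strongly inter-correlated neighbouring temperature windows are —
without the filter a stepwise search can place two nearly collinear
temperature decades in one model with unstable signs. Backward
elimination then starts from the full OLS model and repeatedly
removes the term with the largest p value above alpha_remove = 0.05
(ties: smaller |t|, then later column order, for deterministic
reruns) until every term is significant or one term remains; the full
selection trace is kept on the model object. A p-threshold removal
rule is used; an F-to-remove rule would order removals identically
for single-term steps.

No-intercept models use uncentred total sum of squares for R² and are
flagged, since uncentred R² is not comparable to the intercept-model
quantity; degrees of freedom are n minus the number of terms.
Standard errors come from the unbiased residual variance RSS/df.
Screening is reported for exploration; the modelling path feeds all
varying features to the collinearity filter, so a predictor can enter
a model at alpha_remove = 0.05 even when it misses the stricter 0.01
screening cut.

SPI models can be fitted but are not a supported headline output:
under weather-only predictors their explained variance is low and the
hold-out errors dominate, so the pipeline treats SPI as a descriptive
characteristic.

## Hold-out validation

Models fitted on the training years are applied to the final two
years. Expected values are rounded half-up to integers before
differencing, and observed values likewise — published validation
tables are internally consistent under integer arithmetic, and
rounding after differencing would produce off-by-one disagreements.
The raw model output is retained alongside. The package ships the
published Cracow birch validation table (8 models x 2 years) and its
model equations as fixtures; an audit test confirms all 16
observed/expected/difference triples close exactly.

## Synthetic study conditions

The generator emulates an 18-20-year Central-European monitoring
series; it is the package's test bed, not a climate model.

* **Weather.** Daily cycles interpolate the 12 monthly climate
  normals (Cracow-like station values: January coldest at -1.2 °C,
  July warmest at 19.8 °C, annual humidity ~76 %) between month
  midpoints, then receive a per-month constant correction so that
  every month's zero-noise mean equals its normal exactly.
  Anomalies are AR(1) with phi = 0.8; innovation SDs (2.4 °C
  temperature, 4.7 % humidity, 10.5 % cloudiness, 8.5 % sunshine) are
  calibrated so the inter-annual SD of a generated monthly mean
  (~0.84 x innovation SD) matches the station table's printed SD rows
  for the pre-season months. Sub-daily structure is deterministic
  (fixed diurnal half-ranges with t_min <= t_7, t_19 <= t_max), so
  the derived daily means equal the simulated state exactly.
  Rainfall is a wet-day chain (p = 0.45) with exponential amounts
  matching monthly totals in expectation; amounts below 0.05 mm
  become the 0.01 trace sentinel. Day length follows the standard
  solar-declination formula at 50.07° N.
* **Pollen.** The true season start is
  a0 + a1*Temp_6 + a2*(Hum_10 - normal) + N(0, 2 days), with
  a0 = 102.94, a1 = -1.51 taken from the published one-variable
  season-start model and a2 = 0.59 from the two-variable model. The
  humidity term acts on the anomaly from its climatological normal:
  applied to the raw ~70 % level it would shift the mean start by
  ~+41 days, whereas centring preserves the published mean start
  (~day 101) and leaves both recoverable slopes untouched (the
  centring constant is absorbed by the regression intercept). Starts
  falling outside days 60-150 are resampled (clipped if
  deterministic) with a warning. Daily concentrations follow a
  lognormal-shaped kernel (shape 0.55, mode 8 days after the start,
  1 %-97.5 % span ~29 days, matching a ~31-day 98/95 % season)
  anchored so the kernel's 1 % quantile sits at the true start, and
  are scaled so the central 1-97.5 % mass equals an SPI drawn
  lognormally (log-mean ln 3500, log-SD 0.75, giving CV ~ 80-90 %,
  the observed SPI-vs-start variability contrast). Multiplicative
  day-to-day scatter (log-SD 0.3) and up to 5 stray out-of-season
  grains complete the series.
* **Determinism.** Every year draws from a generator seeded by
  (root seed, year), so extending the series never perturbs earlier
  years, and identical configurations are byte-identical.

What the generator does *not* emulate: multi-day synoptic rain
spells, wind-direction effects and long-distance transport, bimodal
or interrupted seasons, alternation (masting) in pollen production,
and observational error of the volumetric method. Passing tests
therefore demonstrate that the pipeline's statistics behave correctly
under a known unimodal linkage, not that real birch seasons obey one.

Zero-noise configurations are supported as a closure check: with
every noise source at zero all years are identical up to the
leap-year calendar shift, features lose (almost) all variation, the
stepwise model degenerates to a flagged intercept-only or single-term
exact fit, and every hold-out difference is exactly zero after
rounding. Features whose variation is at float precision (< 1e-8
relative) are excluded from selection to keep this regime
numerically sane.

## Problem sizes and numerical choices

The analysis scripts and the acceptance script use a 20-year study
(18 training + 2 hold-out years); oracle and property suites use
1,000 random short series for season bounds, 500 tie-containing
samples for the rank-correlation oracle (agreement to 1e-12), 1,000
null screens for the type-I level (99 % binomial band), and 200
18-year replicates for stepwise linkage recovery — sizes at which the
statistical assertions are stable from run to run. OLS is delegated
to statsmodels and verified against a normal-equations solver to
1e-10; residual orthogonality is asserted to 1e-8. Cumulative
threshold attainment uses exact ">=" comparisons on partial sums;
random-series oracle tests use an epsilon of 1e-12 to absorb float
accumulation differences between oracle and implementation.
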
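# Methods

This note records the statistical model behind `windmatch`, the choices made
where the design was genuinely open, and what the synthetic experiments do
and do not demonstrate.

## Treatment and potential outcomes

A day is treated when its daily-mean wind direction falls in the North-East
sector.  The sector is written 10°–90° in the underlying study design
without an open/closed convention; we use the closed interval [10°, 90°]
(both endpoints treated) and make the sector configurable, including sectors
wrapping through North.  Each day carries fixed potential concentrations
Y(0), Y(1) per pollutant; only one is observed.  All estimands are
finite-sample averages over the matched treated days.

## Daily aggregation and ingestion

Hourly station readings are collapsed to a daily value with a trimmed mean:
with `trim_frac = 0.025`, `floor(n·0.025)` order statistics are dropped from
*each* tail of the non-missing values (per-tail trimming is the common
statistical convention; the total-vs-per-tail reading is ambiguous in the
source design and per-tail was chosen once).  With 24 hourly values nothing
is trimmed, so the rule only bites when several stations' hours are pooled
before aggregation — pooled-then-trimmed is the assumed order.  A day with
more than 3 missing hourly readings is set to missing.

Lags and leads are calendar-based: the lag of day *d* refers to the true
previous calendar day, so a gap in the date index produces a missing lag,
never the previous row's value.  This matters because the matching
constraints reference "the previous day" literally.

## Missing-data imputation

`impute_missing` performs chained (iterative) imputation: median
initialisation, then cycling over incomplete variables fitting a pluggable
regressor on observed rows and predicting missing cells until convergence
(mean absolute change below tolerance) or `max_iter`.  It is backed by
scikit-learn's `IterativeImputer`; the default learner is a small random
forest (30 trees, leaf size 5), with a plain linear learner available for
tests and as a fast option.  This deliberately does not reproduce any
specific chained-forest implementation bit-for-bit.  Excluded variables
(by default PM2.5, which can have very high missingness) are neither imputed
nor used as predictors.  Imputed humidity is clipped to [0, 100], wind
direction to [0, 360), and rainfall categories rounded to {1,…,4}; wind
direction is imputed on the raw degree scale, a known limitation for a
circular variable.  `evaluate_imputation` masks a fraction of observed cells
and reports the mean absolute error per variable, reproducibly per seed.

## Matching

Admissibility of a treated–control pair requires: date gap within [4, 60]
days; equality on weekend, holiday, bank day, rainfall category and the
previous-day treatment indicator; and closed calipers |Δ| ≤ width on
temperature (5 °C), wind speed (0.5 m/s), humidity (12 pp) and previous-day
PM10 (8 µg/m³).  Numeric caliper comparisons carry a 1e-9 slack so that
exact-width differences stored in binary floating point count as inside.
Choices made once:

- The minimum 4-day gap (no-interference filter) is folded into
  admissibility rather than applied after matching; this is equivalent to
  discarding close pairs post hoc but lets the optimizer re-use the freed
  controls.  "Inferior to 4 days" excludes gaps of 1–3 days; 4 is allowed.
- "Less than 0.5 m/s" is treated as ≤ 0.5 for uniformity with the other
  closed calipers (a strict option would change results only on exact-tie
  data).
- The previous-day treatment rule is equality within the pair, with a
  stricter both-untreated option (`lag_w_both_zero`).
- The date distance is the absolute difference in calendar days, so the
  60-day cap never wraps across years: pairs come from the same period of
  the same year.
- A missing covariate needed by any constraint makes the pair inadmissible
  (logged); it is not an error.

The pair distance is a normalized L1 metric: Σ |Δcov| / caliper width over
the caliper covariates plus date gap / 60.  The published algorithm this
emulates does not state its metric, so real-data pair counts may differ
slightly; the metric weights each covariate by the maximum difference the
design itself tolerates.

The matching objective is lexicographic: maximum cardinality first, then
minimum total distance.  It is solved as a single rectangular assignment
problem (`scipy.optimize.linear_sum_assignment`) after pruning isolated
vertices: each treated day may take a real admissible edge at cost equal to
its distance, or a dummy column at a big-M cost exceeding any achievable
total distance (inadmissible edges cost 3M and are never selected because a
dummy is always available).  Minimizing total cost therefore maximizes the
number of real edges before comparing distances.  A bitmask dynamic program
re-derives the optimum exhaustively on small instances in the test suite.
Rows and columns are processed in date order and the solve is
deterministic; among exactly co-optimal matchings no further lexicographic
tie-break is imposed beyond this determinism.

## Balance diagnostics

Continuous covariates are summarized by the absolute standardized mean
difference |mean_t − mean_c| / sd_ref with sd_ref the classic pooled SD
√((s_t² + s_c²)/2) of the *pre-match* treated and control groups, held
fixed for the post-match comparison so the before/after numbers share a
denominator (the source design does not state its denominator; this is a
declared choice).  0.1 is the conventional imbalance flag.  Categorical
covariates are summarized per level by |share_t − share_c| × 100 percentage
points, absent levels counting at share 0.  Monthly stratification applies
only to the pre-match comparison, the view that motivates matching.

## Neymanian analysis

With J matched pairs and observed differences dⱼ:

- τ̂ = mean(d);
- V̂ = Σ (dⱼ − τ̂)² / (J(J−1)), the conservative pairwise variance estimate —
  its expectation is at least the true sampling variance, with equality
  under a constant additive effect;
- CIs use fixed multipliers 1.96 and 2.576 (as conventionally printed,
  not higher-precision normal quantiles; both configurable).

Pairs with a missing outcome value at the requested day offset are dropped
listwise per outcome × offset (the PM2.5 handling), with the dropped count
reported.  The percentage "relative increase" uses the matched control-arm
mean at the same offset as denominator — the natural baseline for "what
these days would have shown", and a declared choice since the source design
leaves its base unstated.  The pairwise-vs-complete comparison estimates the
completely randomized variance as s_t²/J + s_c²/J from the matched arms; a
precision ratio se_complete/se_pairwise above 1 means pairing helped.

## Sensitivity analysis

The quantitative bias analysis uses the Wilcoxon signed-rank statistic
(zeros dropped, ties mid-ranked) with Rosenbaum's worst-case normal
approximation for matched pairs: under hidden bias at most Γ, the
probability each pair's deviation is positive lies in
[1/(1+Γ), Γ/(1+Γ)]; plugging the extremes into the normal null
(E± = p±·Σq, V± = p±(1−p±)·Σq², q the ranks) gives one-sided p-value
bounds.  No continuity correction is applied.  The Γ-adjusted two-sided
interval inverts two one-sided worst-case tests at α/2 each; because the
statistic is constant outside the data range, the bracket
[min d − tol, max d + tol] is exhaustive and endpoints are found by
bisection to 0.01 µg/m³ (an endpoint that never rejects is reported
infinite).  The statistic choice itself is a declared design decision — the
signed-rank construction is the classical matched-pairs method — so
Γ-interval endpoints on other implementations' data may differ slightly.

At Γ = 1 the inversion reproduces the standard signed-rank interval.
Against the exact 2^J distribution (full enumeration, J ≤ 12) the
normal-approximation interval nests just inside the exact one, and its
endpoints stay within one achievable-probability step of the exact
endpoints; on the test data (J = 8–12, differences ~N(5, 3²)) the observed
endpoint gaps were ≤ 0.7 µg/m³.

Negative-control outcomes are the previous-day concentrations: today's wind
regime cannot causally change yesterday's pollution, so a 95% CI excluding
0 at offset −1 flags residual confounding.

## The synthetic generator

The generator emulates, at the daily level, the structure the analysis
assumes for a mid-latitude city on the Paris scale (default 4018 days):

- **Temperature**: annual sinusoid (mean 12.5 °C, amplitude 7.5, late-July
  peak) plus AR(1) noise (coefficient 0.7, innovation sd 2.4).
- **Wind direction**: two-component von Mises mixture — a concentrated
  component centred at 50° (inside the NE sector, κ = 6) and a broad
  prevailing south-westerly component (235°, κ = 1.2).  The NE weight
  follows an annual sinusoid (mean 0.22, amplitude 0.08, spring peak),
  giving ≈ 23% treated days.  NE-component days are cooler by 2 °C and
  drier by 4 pp — the continental-flow signature that creates *observed*
  confounding (pre-match standardized differences ≈ 0.18 on the weather
  covariates) which the matching stage must remove.
- **Wind speed**: gamma(4, 0.9), mean ≈ 3.6 m/s.  **Humidity**: bounded
  seasonal Gaussian.  **Rainfall**: four ordinal categories with fixed
  probabilities.  Calendar indicators use the fixed-date French public
  holidays and bridge days.
- **Pollutants**: Y(0) = intercept + seasonal cycle + temperature and
  wind-speed slopes + AR(1) noise, parameterized to city-background means
  (NO2 ≈ 37, O3 ≈ 40, PM10 ≈ 24, PM2.5 ≈ 14 µg/m³) with winter peaks for
  combustion pollutants and a summer peak for ozone.  Y(1) = Y(0) + τ with
  a constant effect by default (τ = 5 for PM10, 2.5 for PM2.5, 0 for NO2
  and O3); the constant default makes the conservative variance exactly
  unbiased, which sharpens the coverage tests, and a heterogeneous option
  (`tau_sd`) exists for conservativeness experiments.
- **Hidden confounder**: binary U (prevalence 0.2) multiplying each day's
  odds of an NE mixture draw by γ and shifting both potential outcomes by
  δ; U never appears in the observed table.  With γ = 1 and δ = 0 the
  draws coincide exactly with the unconfounded generator.
- **Missingness**: completely at random by default, with a
  temperature-dependent (MAR) option for imputation stress tests.

All randomness flows through named substreams of a single seed, so adding a
feature never silently shifts unrelated draws.

What the generator does *not* emulate: physical atmospheric chemistry,
spatial station structure, hourly dynamics, wind-direction persistence
across days, or long-term trends.  Passing tests therefore show that the
pipeline recovers known effects when its identifying assumptions hold by
construction — not that those assumptions hold in any particular real
dataset.

## Simulation scales and numerical choices

The replicated experiments in the test suite use 200 independent studies of
4000 days for parameter recovery (mean estimate within 2 Monte-Carlo SEs of
the planted τ = 5; 95% CI coverage ≥ 93%) and 200 studies of 1500 days for
the negative-control type-I rate (≤ 10% per pollutant against a nominal
5%); the acceptance script uses one 4018-day study plus 60 replicates of
2000 days, sizes chosen to keep a full reproduction in the minutes range on
one CPU while leaving Monte-Carlo error well below the tested margins.
Bisection tolerances are 0.01 µg/m³ (Γ intervals); caliper slack 1e-9;
imputer convergence tolerance 1e-3.  Degenerate inputs are defined rather
than accidental: all-missing hourly vectors aggregate to missing, an empty
admissible-edge set yields J = 0 with diagnostics (inference is skipped),
constant pair differences give a zero-width interval, and a shift
hypothesis equal to every difference cannot be rejected.

## Known limitations

- The matching metric and solver are declared substitutes for the
  unpublished algorithm the design emulates, so pair counts on real data
  need not reproduce published ones exactly.
- The Γ analysis covers the signed-rank statistic only (no m-statistics,
  no amplification into two-parameter bias models).
- Wind direction is imputed linearly on degrees; days near the 0°/360°
  seam can impute poorly.
- The generator's constant-effect default understates the conservativeness
  of V̂ that heterogeneous real-world effects would induce.
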
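# windmatch

Matched-pair causal inference for the effect of wind direction on daily air
pollutant concentrations.

## The problem

Winds blowing from a polluting sector (here: the North-East of a city, as
for Paris-style particulate transport) are widely used as a source of
quasi-experimental variation in air-pollution epidemiology.  But wind
direction is not randomly assigned: it covaries with season, temperature,
humidity and wind speed, all of which also drive pollutant concentrations.
`windmatch` embeds this observational comparison in a hypothetical pairwise
randomized experiment:

1. **Treatment definition.** Day *i* is treated (Wᵢ = 1) when the wind blows
   from the North-East sector (10°–90°, closed endpoints, configurable).
   Each day has two potential concentrations Yᵢ(1), Yᵢ(0) per pollutant and
   the observed value is Y⁰ᵇˢ = (1−W)·Y(0) + W·Y(1).
2. **Design.** Constrained optimal pair matching without replacement: exact
   match on weekend / holiday / bank-day / rainfall category / previous-day
   treatment, calipers on temperature (≤5 °C), wind speed (≤0.5 m/s),
   humidity (≤12 pp) and previous-day PM10 (≤8 µg/m³), a date gap of at most
   60 days for seasonal comparability and at least 4 days for
   no-interference (SUTVA).  Among admissible pairs the matching maximizes
   the number of pairs, then minimizes total normalized distance.
3. **Analysis.** Neymanian inference on the J matched pairs:
   τ̂ = (1/J) Σⱼ dⱼ with dⱼ the observed pair difference, conservative
   variance V̂ = Σⱼ (dⱼ − τ̂)² / (J(J−1)) (exactly unbiased under a constant
   effect), Gaussian CIs τ̂ ± 1.96·√V̂ (95%) and ± 2.576·√V̂ (99%).
4. **Quantitative bias analysis.** Rosenbaum sensitivity bounds for the
   Wilcoxon signed-rank test: an unmeasured confounder multiplying the
   within-pair odds of treatment by at most Γ yields worst-case p-values
   and Γ-adjusted confidence intervals; previous-day concentrations serve
   as negative-control outcomes, and the pairwise variance is compared with
   the completely randomized one.

A synthetic daily-data generator with known ground truth (seasonal weather,
von Mises wind-direction mixture, AR(1) pollutant baselines, additive
treatment effects, optional hidden confounding) makes every stage testable
without external data.

## Worked example

```python
from windmatch import (SyntheticConfig, generate_dataset, match_pairs,
                       pair_differences, neyman_estimate, sensitivity_interval)

sds = generate_dataset(SyntheticConfig(), seed=1)   # 4018 days, true PM10 effect = 5
pairs = match_pairs(sds.observed)
print(f"J = {pairs.j} of {pairs.n_treated} treated "
      f"(fraction {pairs.matched_fraction:.3f})")
d = pair_differences(sds.observed, pairs, "pm10", 0)
est = neyman_estimate(d, outcome="pm10")
print(f"tau_hat = {est.tau_hat:.2f}  95% CI ({est.ci95[0]:.2f}, {est.ci95[1]:.2f})")
res = sensitivity_interval(d, gamma=2.0)
print(f"Gamma=2 interval ({res.interval[0]:.2f}, {res.interval[1]:.2f})")
```

prints

```
J = 170 of 907 treated (fraction 0.187)
tau_hat = 4.63  95% CI (3.00, 6.26)
Gamma=2 interval (-0.32, 9.81)
```

Of 4018 simulated days, 907 are North-East-wind days and 170 of them have
an admissible control day; the matched estimate recovers the planted
5 µg/m³ effect within its confidence interval, and the Γ=2 interval shows
what an unmeasured confounder doubling the treatment odds could do to it.

The same analysis runs end-to-end from a shell:

```bash
windmatch run --config config.yaml          # all four stages + report
windmatch simulate --n-days 4018 --seed 1 --out daily.csv
windmatch match --input daily.csv --out pairs.csv
```

Real data enter through `read_daily_dataset` (one CSV row per day; column
names mapped via a schema); missing concentrations can be filled by the
chained imputer (`impute_missing`, excluded variables left untouched).

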
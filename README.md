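# ddm — modelling the duration of major depressive episodes

How long does an episode of major depression last? Prospective cohorts
report median recovery times of a few months alongside 10–30% chronicity
(episodes of two years or more) — a strongly right-skewed, long-tailed
duration distribution that ordinary moments describe poorly, and that is
always observed under right censoring because some episodes outlast
follow-up.

`ddm` is a small survival-analysis toolkit for exactly this situation. It
targets duration-event tables (one row per subject: months in episode,
recovered / censored) from two-year follow-up designs and asks which
duration law the data follow:

- **Kaplan–Meier estimation** of S(t) = P(still in episode at t), the
  product-limit estimator S(t) = Π_{tᵢ ≤ t} (1 − dᵢ/nᵢ), with median and
  "fraction recovered by t" summaries;
- **censored maximum-likelihood fits** of three candidate laws, using the
  likelihood ℓ = Σ_events ln f(tᵢ) + Σ_censored ln S(tᵢ):
  exponential S(t) = e^(−t/θ); Weibull S(t) = e^(−(t/α)^β); log-normal
  S(t) = 1 − Φ((ln t − μ)/σ) — compared by AIC = 2k − 2ℓ;
- **probability-paper diagnostics**: each family's axis transform under
  which its survival function is a straight line, scored by the r² of the
  transformed KM points;
- **power-law trend** fitting on double-logarithmic axes
  (log₁₀ S = intercept + slope·log₁₀ t, i.e. S = A·t^(−k)) and the
  differential-equation model behind it, dN/dt = −kN/t — a recovery
  hazard k/t that falls as the episode lengthens — with a numerical check
  that A·t^(−k) solves it;
- **generative mechanisms**: a multiplicative process (product of i.i.d.
  positive factors → log-normal durations) and the same process with a
  lower reflecting barrier and downward drift (→ power-law tail), plus a
  log-log CCDF tail-linearity score to tell them apart.

A synthetic-data module simulates cohorts with the structure such studies
produce (administrative censoring at 24 months, a 0.5-month recording
floor) from any of the four duration laws, and builds a deterministic
90-subject reference cohort whose KM summaries match a published
depression cohort (26% recovered by 1 month, 63% by 3, 85% by 12, 91% by
24; median 3 months).

## Worked example

```python
import ddm

cohort = ddm.make_reference_fixture()          # 90 subjects, 8 censored
report = ddm.run_full_analysis(cohort)

print(report.km["median_months"])              # 3.0
print(report.km["fraction_recovered_by"])      # {'1.0': 0.2556, '3.0': 0.6333,
                                               #  '12.0': 0.8556, '24.0': 0.9111}
print(report.parametric["aic_ranking"])        # ['lognormal', 'weibull', 'exponential']
print(report.probability_paper["r_squared"])   # {'lognormal': 0.974,
                                               #  'weibull': 0.938,
                                               #  'exponential': 0.883}
print(report.power_law["slope"],
      report.power_law["r_squared"])           # -0.668  0.99978
```

Half the cohort has recovered by 3 months; by both AIC and
probability-paper straightness the log-normal law beats the Weibull and
exponential; and the KM points are almost exactly linear on log-log axes
(r² ≈ 0.9998), so a power law S ≈ 0.75·t^(−0.67) describes the observed
range about as well — the log-normal/power-law ambiguity these data
cannot resolve within a two-year window.

The same pipeline runs from a shell:

```sh
ddm simulate --family lognormal --mu 1.15 --sigma 1.14 --n 90 --seed 1 \
    --output cohort.csv
ddm report --input cohort.csv
ddm km --input cohort.csv --plot survival.png
ddm paper-plot --input cohort.csv --figure papers.png
ddm powerlaw --input cohort.csv --check-ode
```

Input CSVs have the header `time_months,event` with `event` 1 = recovered,
0 = right-censored.

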
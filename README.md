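# pulseval

Criterion-validity analysis for optical (photoplethysmographic) heart-rate
wearables, built for exercise-laboratory studies that ask two questions:
*how well does a wearable track a criterion HR monitor across rest,
graded exercise and recovery?* and *does skin pigmentation degrade its
accuracy or data quality?*

The package provides, as a reusable library plus a small CLI:

* **Colorimetry** — skin pigmentation from CIELAB colorimeter readings as
  the Individual Typology Angle,
  `ITA° = arctan((L* − 50) / b*) · 180/π`,
  computed from channel means of replicate readings; subjects with a mean
  device-site ITA° below 10° are classified dark-skinned.
* **HR pipeline** — plausibility screening (drop HR < 50 or > 200 bpm),
  averaging of heterogeneous streams into half-open 30-s epochs, timestamp
  matching of device to criterion epochs, missing-epoch accounting with
  dark-skin attribution, and outlier flagging at 3.29 × SD of the pooled
  per-device signed error.
* **Agreement statistics** — repeated-measures Bland–Altman limits of
  agreement (`bias ± 1.96 · s`, with `s² = σ²_between + MS_within` from a
  one-way ANOVA of differences on subject and the unequal-replicates
  correction `n₀`), agreement grading (LoA ≤ 5 bpm excellent, ≤ 10 bpm
  good, else unacceptable), proportional bias as the Pearson trend of the
  difference against criterion HR, the repeated-measures correlation
  `r_rm` from the common-slope ANCOVA, MAE by intensity, repeated-measures
  ANOVA with Greenhouse–Geisser correction, and Bonferroni pairwise tests.
* **Error model** — a Gaussian random-intercept mixed model of the per-epoch
  absolute error, `MAE_HR,ij = β₀ + β₁·ITA°ᵢ + β₂·HRij + bᵢ + εij`, fitted
  by profiled maximum likelihood with forward entry by likelihood-ratio
  test, plus ICC, marginal R², squared semi-partial correlations and VIF.
* **Synthetic study generator** — a bimodal-pigmentation cohort, 1-Hz
  criterion traces over a rest / 4 × 10-min graded-cycling / recovery
  protocol, and device streams with configurable bias, proportional bias,
  subject heterogeneity, pigmentation-linked noise, epoch missingness and
  outliers, so every estimator can be validated against known ground truth.

## Worked example

Simulate a small five-subject study, analyze it, and render the report:

```sh
pulseval simulate --seed 7 --out demo --n-subjects 5
pulseval analyze --hr demo/hr_streams.csv --colorimeter demo/colorimeter.csv --out demo/bundle
pulseval report --bundle demo/bundle
```

prints

```
Device validation summary
=========================

Agreement vs criterion (bias / 95% LoA, bpm):
  armband: bias -0.0, SD 4.0, LoA [-7.8, 7.7], trend r 0.16, grade good
  watch_a: bias +0.2, SD 1.2, LoA [-2.2, 2.5], trend r 0.11, grade excellent
  watch_b: bias +0.3, SD 2.3, LoA [-4.3, 4.9], trend r 0.02, grade excellent
...
Mixed-effects error models (MAE_HR ~ pigmentation + HR):
  armband: constant 3.24, ita -0.0095; ICC 0.012, marginal R2 0.018
  watch_a: constant 0.97; ICC 0.000, marginal R2 0.000
  watch_b: constant 1.85; ICC 0.000, marginal R2 0.000
```

Reading the output: the simulated arm-band is configured with the largest
noise and a pigmentation-linked noise term, so its limits of agreement are
wider (grade *good* rather than *excellent*) and forward entry retains a
negative ITA° coefficient — darker skin (lower ITA°) predicts a slightly
larger absolute error, about 1 bpm across a 100° pigmentation span. The two
simulated watches show no pigmentation effect, and their LoA stay within
±5 bpm. Every number in the report is read from the machine-readable CSV/JSON
artifacts in `demo/bundle/`.

The same analysis is available as a library:

```python
import pulseval as pv

study = pv.generate_study(seed=42)                     # 28 subjects, 4 devices
result = pv.analyze_study(study.hr_samples, study.colorimeter)
print(result.agreement_table[["device_id", "bias", "sd", "grade"]])
```

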
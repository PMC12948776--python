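# Methods

This note documents the statistical procedures, the synthetic-data
generator and the numerical conventions used by `pulseval`, in the package's
own words. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Pigmentation quantification

Skin pigmentation is summarized as the Individual Typology Angle,
`ITA° = arctan((L* − 50)/b*) · 180/π`, from CIELAB colorimeter readings.
Replicate readings (triplicates in the reference protocol) are averaged
**per channel** first and ITA° is computed from the averaged `L*`/`b*`;
averaging per-replicate angles instead would give a different, nonlinear
summary, and a regression test asserts the channel-first convention.

Classification uses the mean ITA° over the device placement sites (both
wrists and the lateral upper arm); the volar arm is a sun-protected
standardization site, reported in summaries but never entering the
classifier. The dark-skin rule is **strict**: `mean_device_ita < 10°`. The
threshold is configurable (`dark_threshold`); 10° is the conventional cut
between *tan* and *brown/dark* typology categories. Degenerate colorimetry
(`b* = 0`) is an error rather than ±90°, because it indicates an invalid
reading; `b* < 0` is allowed with a warning (the angle's sign flips).

## HR stream pipeline

* **Plausibility screen**: samples with HR < 50 or > 200 bpm are removed
  (bounds retained). Applied uniformly to criterion and device streams;
  manual-inspection removals used in laboratory practice are deliberately
  not emulated beyond this rule.
* **Epochs**: half-open 30-s windows `[origin + 30i, origin + 30(i+1))`
  anchored at the session origin, taken as the start of the subject's
  criterion recording and shared by all devices of the session (devices are
  assumed clock-synchronized; a per-device offset could be added upstream
  of matching if needed). One sample suffices to define a non-missing
  epoch; no interpolation is performed across gaps.
* **Matching**: inner join of device on criterion epoch index; epochs
  missing on either side are excluded and counted. Each matched epoch is
  labelled with the protocol stage covering its start time (an epoch
  straddling a stage transition belongs to the earlier stage by the
  half-open convention).
* **Missingness accounting**: missing = expected-per-protocol minus
  non-missing, per subject, pooled per device; the dark-skin attribution is
  the share of all missing epochs belonging to dark-classified subjects.
* **Outliers**: an epoch is flagged when its signed error deviates from
  the per-device mean error by more than `k·SD`, `k = 3.29` (the two-sided
  0.1% point of the normal). The rule is applied once, pooled per device
  across subjects and intensities, with no re-estimation after removal;
  under Gaussian errors the expected flag rate is `2(1 − Φ(3.29)) ≈ 0.001`,
  which the suite verifies empirically. Zero error SD yields no flags.

## Agreement statistics

* **Repeated-measures Bland–Altman** (varying-true-value variant, suited to
  a graded-exercise protocol): a one-way ANOVA of the differences on
  subject gives `MS_between` and `MS_within`; with replicate counts `mᵢ`,
  `n₀ = (Σmᵢ − Σmᵢ²/Σmᵢ)/(k − 1)`,
  `σ²_b = max(0, (MS_between − MS_within)/n₀)` and the SD of a single
  difference is `√(σ²_b + MS_within)`. Limits of agreement are
  `bias ± 1.96·SD`. With exactly one difference per subject the estimator
  degenerates to the classic sample SD. The truncation guarantees
  `SD ≥ √MS_within`.
* **Grading** reads the larger absolute limit: ≤ 5 bpm excellent (5% error
  at 100 bpm, consistent with the ±5 bpm consumer-device standard),
  ≤ 10 bpm good, wider unacceptable. Thresholds are configurable.
* **Proportional bias** is the pooled Pearson correlation between the
  difference and criterion HR (the abscissa of a modified Bland–Altman
  plot), with the pooled-df two-sided p value; within-subject correlation
  of epochs makes this p value anticonservative, which is accepted as the
  plot-level convention. Constant differences make the trend undefined and
  it is reported as not applicable.
* **r_rm**: both variables are centred within subject;
  `SS_measure = (Σx̃ỹ)²/Σx̃²`, `SS_error = Σỹ² − SS_measure`,
  `r_rm = sign(Σx̃ỹ)·√(SS_measure/(SS_measure + SS_error))`,
  `df = N − k − 1`, p from `F(1, df)`. Equivalent to the common-slope
  ANCOVA and cross-checked against `pingouin.rm_corr` in the suite.
* **Intensity comparisons**: per device × stage mean/SD of the absolute
  epoch error; one-way repeated-measures ANOVA on per-subject stage means
  (listwise deletion of subjects with empty cells, logged); the
  Greenhouse–Geisser epsilon is estimated from the double-centred
  condition covariance and the corrected df/p are always reported alongside
  the uncorrected ones — the corrected p is the conservative choice
  whenever ε < 1, which operationalizes "correct when sphericity is
  violated" without a separate Mauchly gate. Pairwise comparisons use
  paired t tests with Bonferroni multiplication capped at 1. Degenerate
  paired t inputs are explicit: zero difference variance with zero mean
  gives `t = 0, p = 1`; with nonzero mean, `t = ±∞, p = 0`.

## Mixed-effects error model

`MAE_HR` per matched, outlier-free 30-s epoch is the response of a Gaussian
random-intercept model. The marginal covariance is
`σ²_e I + σ²_b Z Zᵀ` with `Z` the subject indicator. Fitting profiles `β`
and `σ²_e` analytically and minimizes the negative profile log-likelihood
over `log λ`, `λ = σ²_b/σ²_e`, with a bounded scalar search on
`log λ ∈ [−30, 15]`; per-group algebra (`V_g⁻¹ = I − λ/(1+λm_g)·J`) makes
each evaluation O(n). A boundary solution is reported as exactly
`σ²_b = 0`, and the likelihood can never fall below the OLS likelihood
(nesting), which the suite asserts. **ML, not REML**, throughout, so that
likelihood-ratio tests between fixed-effect structures are valid; variance
components are therefore slightly biased downward at small k, accepted by
design. Wald SEs come from `σ²_e (XᵀV⁻¹X)⁻¹`; coefficient p values are
secondary to the LRT decisions. One observation per subject makes `σ²_b`
unidentifiable: the fit warns and returns OLS.

**Forward entry**: starting from intercept-only, candidates are tried in a
fixed order — pigmentation (ITA°) first, then criterion HR — and kept iff
the LRT p < α (default 0.05). The selection trace (χ², df, p, kept) is part
of the output bundle.

Derived statistics:

* **ICC** `= σ²_b/(σ²_b + σ²_e)` from the intercept-only fit (share of
  variance at the participant level). Location/scale invariant.
* **Marginal R²** `= Var(Xβ̂)/(Var(Xβ̂) + σ²_b + σ²_e)` with the variance
  of the non-intercept fixed-effect predictor taken over the observed
  design.
* **sr²**: the drop in marginal R² when one predictor is removed and the
  model refitted, floored at 0. There is no unique mixed-model definition
  of a squared semi-partial correlation; this marginal-R²-difference
  convention is adopted and labelled as such. For orthogonal predictors the
  sr² values sum to the marginal R² (verified by simulation).
* **VIF** `= 1/(1 − R²_j)` from OLS of predictor j on the rest; a single
  predictor has VIF 1; perfect collinearity reports ∞ with a warning.

## Synthetic study generator

The generator's defaults encode the reference study conditions; they are
fixed study parameters, not tuning knobs.

* **Cohort** (n = 28): pigmentation is a two-component mixture over the
  device-site ITA° — a dark component (weight 10/28 ≈ 0.36, mean −36.8°,
  SD 16.3°) and a non-dark component (mean 38.9°, SD 13.9°) whose
  parameters are solved so the pooled device-site mean/SD land near
  11.9°/39.2°. Components are truncated 2° away from the 10° threshold so
  that site-level noise (SD 3°) cannot flip a subject's intended label;
  the tails lost to truncation are negligible at these component means.
  The volar site is shifted +19.5° (sun-protected skin is lighter). Age is
  N(25, 5) clipped to 18–59 with HRmax = 208 − 0.7·age; resting HR is
  N(69, 12) clipped to 45–100.
* **Criterion trace** (1 Hz, 3300 s): resting HR for 5 min; four 10-min
  stages ramping linearly over 2 min to 50/60/70/80% of HRmax and holding;
  recovery decaying exponentially (τ = 150 s) toward resting + 30 bpm,
  ending near ~100 bpm for a typical subject; AR(1) fluctuation throughout
  (stationary SD 2 bpm, lag-1 correlation 0.9); clipped to
  [40, HRmax + 5].
* **Device streams** sample the criterion at the device interval (5 s;
  uniform 2–15 s; 10 s for the three default devices) and add: constant
  bias (0.0 / 0.4 / 0.7 bpm), proportional bias referenced to 120 bpm
  (slopes 0.004 / 0.003 / 0.027 bpm/bpm, chosen so that pooled trend r
  lands near 0.1 / 0.04 / 0.18 given each device's noise), per-subject
  intercepts (SD 0.3 / 0.5 / 0.8 bpm), white sample noise whose SD is set
  so the epoch-level difference SD lands near 1.1 / 2.0 / 3.7 bpm after
  epoch averaging (per-sample SD 2.7 / 3.7 / 6.0 bpm), and for the
  arm-band an extra noise SD of 0.024 bpm per degree of ITA° below 10°
  — chosen so the induced slope of the epoch-level absolute error on ITA°
  is near −0.011 bpm/° (E|N(0,σ)| = σ√(2/π), and epoch averaging over ~3
  samples shrinks the per-sample term by √3). Missingness is injected at
  whole-epoch granularity (the unit in which data loss is counted) with
  base probabilities 0.055 / 0.20 / 0.047 and dark-skin multipliers
  1.8 / 1.0 / 10, reproducing overall missing rates near 7% / 20% / 20%
  with dark-skin attributions near 50% / 36% / 85%. Outlier spikes of
  ±25 bpm occur per sample with probability 0.002 / 0.004 / 0.006.
* **Colorimeter files** invert each site's target angle: `b*` drawn in
  [10, 22] (shrunk for extreme angles to keep `L*` in [0, 100]),
  `L* = 50 + b*·tan(ITA°)`, triplicates with channel noise SD 0.5.
* **Determinism**: one global seed expands to per-subject/per-device child
  seeds by fixed integer arithmetic, so any subset of a study regenerates
  identically and `simulate` is byte-deterministic.

What the generator does **not** emulate: motion artifact and its
interaction with pigmentation; beat-level RR dynamics or raw PPG
waveforms; device firmware quirks (dropout bursts, smoothing filters);
pigmentation-linked *outlier* excess for devices without the
pigmentation-noise term (the error configuration deliberately exposes only
an extra-noise channel, so simulated dark-skin outlier disproportion arises
only where that term is active). Passing tests therefore demonstrate
correctness of the estimators under a plausible error model, not device
behaviour in the field.

## Problem sizes and runtime conventions

Simulation-based checks run at the study's natural scale — 28 subjects with
~100 usable epochs each — with 200 replicates for the selection
operating-characteristic checks and 500 replicates for the
limits-of-agreement coverage calibration; these sizes give Monte-Carlo
standard errors comfortably inside the asserted tolerances while keeping
the whole suite fast. Test tolerances for stochastic recoveries are set at
~3 Monte-Carlo standard errors of the quantity under its generating
parameters.

## Known limitations

* The proportional-bias p value ignores within-subject correlation.
* Confidence intervals for the LoA themselves are out of scope, as are
  Lin's concordance and mixed-model Bland–Altman variants.
* The mixed model assumes Gaussian residuals although per-epoch absolute
  error is non-negative and right-skewed; this mirrors common practice and
  the LRT-based selection is robust at these sample sizes, but coefficient
  SEs should be read accordingly.
* Exact epoch-mean equality between a subsampling device and the criterion
  holds only when HR is constant or sampling rates match; during ramps a
  subsampled epoch mean differs slightly from the full-rate mean. This is
  a property of real epoching, not an artifact.
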
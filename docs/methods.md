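# Methods

## The score and its estimation

The package studies multiplicative combinations of the three serum PSA
fractions, `score = α · X^a · Y^b · Z^c` with X = tPSA, Y = fPSA,
Z = cPSA. Taking logs, a logistic model for P(PCa) with linear predictor
`β0 + a·log X + b·log Y + c·log Z` makes (a, b, c) ordinary logistic
coefficients; they are estimated by maximum likelihood using iteratively
reweighted least squares (damped Newton steps, convergence at a relative
step norm below 1e-10). `α = exp(β0)` is reported but never used for
ranking metrics: any strictly increasing transform of the score leaves
the ROC ordering unchanged, which also means the exponents are only
identified up to a positive scaling. `canonicalize_exponents` therefore
divides by the tPSA exponent (fixing a = 1), drops α, and snaps each
exponent to the nearest multiple of 0.5 (grid configurable). The
canonical form of the reference direction is the PCP score
`tPSA/fPSA · √cPSA`, i.e. (a, b, c) = (1, −1, 0.5).

Two numerical guards matter here:

- **Ridge penalty.** Because cPSA ≈ tPSA − fPSA, the three log-markers
  are nearly functionally dependent; a ridge penalty of λ = 1e-4 on the
  exponents (never the intercept) keeps the IRLS solve well-conditioned.
  At this magnitude the penalty is far below the Fisher information of
  any identified direction and does not move the canonical rounding.
- **Separation.** A fit that classifies every training subject correctly
  means the classes are linearly separable in the log-markers; the
  likelihood then has no interior maximum (the ridge pins it at a finite
  but arbitrary point), so such fits are flagged `status="separation"`
  and excluded from bootstrap summaries.

**Identifiability under the additive constraint.** On cohorts that obey
cPSA ≈ tPSA − fPSA to within assay noise, the residual variation of
log cPSA given the other two log-markers is only the ±2–5% additivity
noise, so the cPSA exponent is very weakly identified — single-cohort
estimates of (a, b, c) scatter widely along the near-null direction even
at n in the thousands. Exponent-recovery checks therefore use
`sample_power_direction`, which draws log-marker triplets from a
well-conditioned trivariate Gaussian whose between-class mean shift is
`Σβ` with β ∝ (1, −1, 0.5): by the equal-covariance Gaussian
discriminant identity the population log-odds is exactly linear with
coefficient β, and all three exponents are identifiable. These draws
deliberately relax the additivity constraint and are labelled synthetic;
they are ground truth for the estimator, not a model of PSA chemistry.
On realistic additive cohorts the meaningful, stable object is the
ROC-relevant direction after canonicalization, which is exactly what the
bootstrap stability report (`exponent_stability`) quantifies.

## The synthetic cohort generator

The generator emulates a biopsy-confirmed clinical cohort of men with
tPSA 2–20 ng/mL: two strata [2,10) and [10,20) ng/mL with fixed
per-group counts (PCa 54/48, BPH 579/147; n = 828, prevalence 12.3%).
Per group:

- tPSA is lognormal truncated to the stratum bounds (inverse-CDF
  sampling; a truncation mass below 1e-9 is a configuration error). The
  same parent log-location/scale is shared by both strata.
- %fPSA is Beta(mκ, (1−m)κ) with mean m and concentration κ,
  independent of tPSA; fPSA = %fPSA · tPSA.
- cPSA = (tPSA − fPSA)(1 + ε), ε uniform on ±2% by default (the free
  and complexed fractions sum to the total only approximately; records
  enforce agreement within 5%).
- age is Normal(71.6, 7) truncated at 40, identical across groups — the
  reference cohort shows no age difference (71.7 vs 71.5 years).

**Calibration.** `calibrate_generator` matches each group's medians of
tPSA and %fPSA to target values by deterministic root finding: the
pooled tPSA median of the stratum-count-weighted truncated-lognormal
mixture is solved for the log-location with Brent's method on the
analytic CDF, and the Beta mean is solved from the exact Beta median.
The fPSA and cPSA medians are not free parameters — they emerge through
the multiplicative construction — and the result is verified on a
simulated draw of 10,000 subjects per group (stratum proportions
preserved, largest-remainder rounding): every targeted marker median
must land within 10% relative error or calibration fails with
per-marker diagnostics. Under the default targets (PCa 9.2/1.0/8.0/0.13,
BPH 5.5/1.0/4.4/0.19 for tPSA/fPSA/cPSA/%fPSA) all four medians pass,
and the group PCP medians emerge near 21 and 11.4 against the reference
22.1 and 11.0 without ever being targeted.

**Dispersion defaults.** The tPSA log-scale (0.5) and %fPSA
concentration (15) control within-group spread and hence per-marker
discrimination. They were fixed once so that, with medians calibrated,
the simulated per-marker AUCs approximate the reference cohort's
reported pattern (PCP ≈ 0.68–0.72 > %fPSA ≈ 0.67–0.69 > cPSA > tPSA ≈
0.54–0.64 per stratum); they are part of the emulated study conditions,
not tuning knobs.

**What the generator does not reproduce.** Real %fPSA declines with
tPSA; here the ratio is independent of tPSA within a group, which makes
within-stratum fPSA slightly *lower* in cancer and its higher-oriented
AUC fall below 0.5, where the reference cohort reports a weakly positive
fPSA AUC (0.571/0.643). No correlation with age, prostate volume or
pathology grade is modelled. Passing tests on these cohorts establish
that the estimators and the operating-point arithmetic behave correctly
under the stated marker structure — not that PCP's clinical advantage
would replicate in any particular population.

## Diagnostic evaluation

- **Univariate logistic fits** use statsmodels' ML Logit; odds ratios
  are per unit of marker with Wald 95% CIs (`exp(slope ± 1.96·SE)`) and
  two-sided Wald p-values, displayed as "<0.001" below 0.0005.
  Separation falls back to a lightly ridged IRLS fit and is flagged.
- **ROC/AUC.** ROC curves sweep every distinct score value as a
  threshold ("positive" = score ≥ threshold) plus ±∞ sentinels, so the
  curve always spans (sens 0, spec 1) to (sens 1, spec 0). Markers
  where low values indicate disease (%fPSA) are negated internally
  (`lower_is_positive`). The AUC is computed in the Mann–Whitney form
  with mid-rank tie handling and equals the trapezoidal area under the
  curve to 1e-12.
- **Bootstrap.** Resampling is stratified within diagnosis class (at
  8.5–25% prevalence an unstratified resample can lose the case class),
  B = 1,000 by default, percentile CIs; every routine takes an explicit
  seed and is reproducible bit-for-bit.
- **Hosmer–Lemeshow.** Subjects sorted by fitted probability are split
  into g = 10 near-equal groups (ties stay together in the lower group;
  groups whose mean risk is exactly 0 or 1 are merged into a
  neighbour), statistic `Σ (O−E)²/(n π̄(1−π̄))` on g−2 degrees of
  freedom. In-sample, on a correctly specified model, its p-values are
  approximately uniform (verified by simulation). The bootstrap variant
  (resample → refit → HL on the refit's fitted probabilities), exposed
  for histogramming, is **anti-conservative by construction**:
  duplicated subjects overdisperse group counts relative to the
  binomial variance in the denominator, shifting p-values well below
  uniform even for a perfectly specified marker. Both paths are
  available; calibration conclusions should rest on the in-sample test.
- **AUC differences** (`compare_aucs`) use a paired bootstrap (shared
  resample indices for both markers); the difference is called
  significant when the percentile CI excludes 0. This is plumbing for
  convenience, not a published testing procedure.

## Operating points

Three levels per marker: (I) the threshold giving the *least achievable*
sensitivity at or above the target (default 0.90) — achieved
sensitivities are exact fractions m/n_pos, which with 54 and 48 cases
yields 49/54 = 90.7% and 44/48 = 91.7%; ties resolve toward higher
specificity; (II) the maximum of Youden's J = sens + spec − 1, ties
toward higher sensitivity; (III) the mirror of (I) on specificity
(default target 0.90). Reported cut-offs are midpoints between adjacent
distinct scores, so "score ≥ cut-off" reproduces the tabulated
sensitivity/specificity exactly regardless of inequality conventions;
percentages print to one decimal, half-up.

## Problem sizes

Defaults used by the test suite and the acceptance script: calibration
verification and emergent-median checks at 10,000 subjects per group;
exponent recovery averaged over 50 simulations at 2,000 subjects per
group; bootstrap-CI coverage measured over 200 repetitions at 500
subjects per group with B = 1,000. These sizes put Monte-Carlo error
well inside the stated tolerances while keeping a full run in the
tens of seconds on one CPU.

## Known limitations

- The reference study's patient-level data are unavailable; its exact
  AUCs, cut-offs and specificities cannot be reproduced numerically,
  only directionally on calibrated synthetic cohorts.
- Whether the reference descriptive medians were computed pooled or per
  stratum is not stated; this package pools the 2–20 ng/mL cohort for
  the descriptive table and calibration, and evaluates per stratum.
- Exponent estimates on additive cohorts are reported with their
  bootstrap spread rather than a single point value, for the
  identifiability reason above.
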
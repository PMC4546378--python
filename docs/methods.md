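# Methods

## The analysis problem

A four-period single-ascending-dose crossover in healthy volunteers
(placebo, 500, 600, 800 mg; ~32 subjects) measures triplicate 12-lead ECGs
at 19 nominal times (pre-dose to 96 h) on a drug-free baseline day (Day -1)
and the dosing day (Day 1) of every period, with PK samples time-matched to
the ECGs. The questions are (i) whether the drug prolongs the heart-rate-
corrected QT interval, assessed both per time point and through
concentration-QTc (C-QT) regression, and (ii) whether the assay could have
detected a small QTc change at all — shown here without a pharmacological
positive control, using the reliable postprandial QTc shortening after a
standardised lunch.

## ECG reduction and heart-rate correction

Each (subject, period, day, time) cell carries three 10 s ECGs; QT and RR
are reduced by their medians independently (an even count averages the two
central values). QTcF = QT/RR^(1/3), RR in seconds; the exponent is
configurable (0.33 reproduces analyses that used the two-decimal constant —
the difference is < 0.5 ms at physiological RR).

The individual correction (QTcI) is fitted per subject on all drug-free
replicate-level records: Day -1 of all four periods plus the placebo-period
Day 1. Replicate-level points (rather than medians) are used because they
triple the fitting data; this is configurable upstream by pre-reducing the
table. Two candidates are fitted by least squares — linear
`QT = a + b·RR` (QTcI = QT − b·(RR−1)) and log-log `ln QT = a + b·ln RR`
(QTcI = QT/RR^b) — and chosen by: (1) smaller |Pearson r| between QTc and
RR, (2) smaller |slope| of QTc on RR, (3) log-log. Ties use an absolute
tolerance of 1e-9: the linear candidate's correlation is *exactly* zero by
least-squares orthogonality whenever it is evaluated on its own fitting
data, so a tolerance at rounding-noise level (1e-12) would turn the rule
into "always linear" even on data generated from an exact power law. A
subject with fewer than 20 drug-free pairs or constant RR falls back to
Fridericia, flagged.

A structural note that matters when interpreting QTcI analyses: if the true
QT is multiplicative (QT = QTc·RR^b) and a drug shifts QTc additively, the
*linear* correction transmits that shift scaled by ≈ RR̄^b (≈ 0.97 at
RR̄ = 0.9 s), a ~3-4% attenuation of any fitted concentration slope. The
Fridericia and log-log corrections do not have this bias. The slope-recovery
validation therefore uses the Fridericia endpoint; QTcI results inherit the
small attenuation by construction, exactly as they would in a real study
whose selection rule lands on the linear form.

## Endpoints

QTc^baselineAV per subject-period = mean over Day -1 per-time medians;
ΔQTc(t) = QTc(Day 1, t) − QTc^baselineAV; ΔΔQTc(dose, t) = ΔQTc(dose, t) −
ΔQTc(placebo, t) matched on nominal time within subject (missing placebo
cells are left missing, never imputed).

## Per-time-point model

`ΔQTc ~ sequence + period + sex + treatment*time + baseline` with a random
subject intercept, REML. "Compound symmetry" is realised as the random
intercept (the induced covariance is identical). Time is categorical with
pre-dose as reference; the baseline covariate is grand-mean-centred for
numerical stability. Dose-vs-placebo contrasts at each post-dose time use
two-sided 90% t CIs with (N_obs − rank of the fixed design) degrees of
freedom — at ~2,400 observations the difference to a Satterthwaite
approximation is negligible. The largest time-matched difference per dose is
taken over post-dose times ≤ 24 h (configurable); exact ties resolve to the
earliest time. Under the null this maximum is positively biased, which the
tests document rather than correct.

## Concentration-effect models

Series 1 (ΔΔQTc-based): `ΔΔQTc ~ conc (+ period + sequence + sex)`;
variants 1/2 add a random intercept / intercept+slope; variant 3 drops all
fixed effects except the slope, constrains the fixed intercept to 0 and
keeps random intercepts and slopes. Series 2 (ΔQTc-based):
`ΔQTc ~ time + period + sequence + sex + conc` over active *and* placebo
rows (placebo concentration 0); the time factor absorbs the spontaneous
course (meals included), so the slope is placebo-corrected by construction;
variants 1/2 as above.

Numerical choices: concentrations are standardised to unit SD inside the
model — raw ng/mL slopes have variance ~1e-8 and defeat the optimiser — and
slopes are reported back in ms per ng/mL; this also makes fits exactly
invariant to rescaling the concentration units. Fixed-effect covariances
are computed as the GLS form (Σ X'V⁻¹X)⁻¹ at the estimated variance
components rather than from the optimiser's Hessian, which is singular when
a variance component sits on its boundary — the usual situation for
change-from-baseline endpoints, where the subject level largely cancels.
The optimiser walks lbfgs → bfgs → cg → powell and keeps the first
converged finite fit.

AIC: model selection uses ML refits by default (restricted likelihoods are
not comparable across different fixed-effect structures; series-1 variant 3
has a different fixed part). The REML-likelihood AIC is also computed, and
selection can be switched to it to mirror analyses that compared
REML AICs directly. AIC counts fixed effects + variance parameters +
residual variance. Ties prefer fewer variance parameters.

Slope inference is design-robust: the slope SE comes from the subject-level
sandwich covariance with the Bell-McCaffrey CR2 leverage adjustment
(computed in the whitened model), with a two-sided t CI on
n_subjects − 1 degrees of freedom. The rationale: a concentration slope's
uncertainty at ~32 subjects is dominated by between-subject response
heterogeneity, and the plug-in GLS covariance of a random-effects fit
understates it whenever the REML variance components are themselves noisy —
calibration runs put the plug-in 90% CI near 80-87% coverage versus 85-93%
for the robust CI under the generator's defaults. Within-subject quantities
(series-2 time effects, per-time treatment contrasts) keep the model-based
GLS covariance, which is well calibrated there.

Predictions at the geometric-mean Cmax: for series 2 and series-1 variant 3
the drug effect at concentration C is slope·C (all other terms are shared
between a treated and an untreated subject and cancel); series-1 variants
1-2 add the fixed intercept, because their printed slope alone does not
reproduce a placebo-corrected prediction. Prediction CIs use the same
robust covariance and degrees of freedom as the slope. If |prediction| > 5 ms the CI is recomputed by a
subject-level bootstrap (resampling stratified by sequence, default
B = 1000, percentile interval) that refits the model *and* recomputes the
geometric-mean Cmax per replicate, carrying the sampling variability of the
mean exposure that the parametric CI ignores.

## Assay sensitivity

From the series-2 fit (QTcF by default; the time-factor model), the
contrasts of 6 h and 8 h versus pre-dose get fixed two-sided 95% CIs — 95%
rather than 90% as a Bonferroni correction for exactly two pre-specified
times; the level does not adapt if other times are requested unless
overridden. The criterion: every CI entirely below 0 *and* every point
estimate ≤ −5 ms ("well below −5 ms" operationalised as ≤ −5.0 exactly,
configurable). Single-trial analyses select the series-2 variant by AIC;
the Monte-Carlo power loops pin variant 1 (random intercept) for run time —
the time contrasts are insensitive to the random-slope term.

## Non-compartmental analysis

Cmax/tmax by direct maximum (tie → earliest). AUC by linear-up/log-down
trapezoids (log interpolation only on declining strictly-positive
segments), to the last positive concentration (AUC0-t), to 24 h with
interpolation if needed (AUC0-24), and extrapolated as AUC0-t + Clast/λz
(AUC0-∞). λz is the best adjusted-R² log-linear fit over candidate tails of
3-8 points strictly after tmax with negative slope; t½ = ln2/λz; failures
leave t½/AUC0-∞ missing and flagged. Pre-dose concentrations are fixed at 0
(single-dose periods). Dose-group summaries report mean (SD), median (SD)
for tmax, the geometric-mean Cmax for the prediction stage, and
dose-normalised columns dividing by the row's own dose; a
`normalize_reference_mg` switch reproduces summaries normalised to a fixed
reference dose (some reports normalise the higher doses to the lowest dose
rather than the row dose).

## Synthetic-trial generator

The generator emulates the trial's statistical structure, not its raw data:

- **Design**: the four ascending-dose sequences with rotating placebo,
  subjects allocated round-robin; sex alternates by allocation round
  (blocks of four) — per-subject alternation would make sex a deterministic
  function of sequence and alias the two factors in every model.
- **PK**: one-compartment, first-order absorption; defaults ka = 1 /h,
  t½ = 35 h, V/F = 118 L so that 500 mg peaks near 3.9 µg/mL, dose
  proportional, with a per-subject lognormal exposure multiplier
  (CV 0.2, shared across periods and analytes). Optional metabolites are
  scaled parent curves (default factor 0.15 when enabled).
- **QT model**: true QTc = subject level (population mean 410 ms, between-
  subject SD 8 ms, +10 ms for women) + optional cosine circadian term
  (amplitude 0 by default, 24 h period, night-time acrophase) + postprandial
  term + drug_slope·C(t); observed QT = true QTc · RR^b_subject + replicate
  noise (SD 5 ms), with per-subject exponents b ~ N(0.32, 0.04), RR around a
  subject mean of 0.90 s (between-subject SD 0.07 s, within 0.05 s) and a
  transient postprandial RR drop of 0.04 s. Replicate SD and RR spreads are
  plausible Phase-I magnitudes chosen once; the trial report does not state
  them.
- **Food effect**: amplitude·exp(−(t − t_meal)/decay) from each meal (5 and
  9 h, both days). Default amplitude −8 ms; default decay 16 h — the
  reported postprandial contrasts (−8.1 ms at 1 h post-meal, −7.2 ms at
  3 h) imply a decay constant near 2/ln(8.1/7.2) ≈ 17 h, and a fast decay
  (e.g. 4 h) would leave the 8 h point near −3.8 ms, below any −5 ms
  detection threshold and inconsistent with the meal test being usable at
  both times.
- One optional dropout (default off) mirrors a 31/32 completer pattern.

All randomness flows from explicit integer seeds; identical inputs give
bit-identical tables.

What the generator does *not* emulate: waveform-level morphology and
measurement artefacts, circadian structure by default, QT-RR hysteresis,
autonomic states (sleep/posture), exposure-dependent absorption delays from
meals, or non-linear C-QT relationships. Passing tests therefore validate
the statistical machinery under the stated generative assumptions, not the
behaviour of any real compound.

## Validation sizing

Monte-Carlo validation in the test suite uses 200 simulated 32-subject
trials for slope recovery/coverage (random-slope variants, Fridericia
endpoint), assay-sensitivity power and specificity (variant-1 series-2
fits), and double-difference nulling. Supporting unit-level Monte-Carlo
checks (per-time CI coverage of the timecourse model) run on reduced trials
(8 subjects, 6 time points, 40 replicates, pooled intervals) as the
package's own sizing for a fast default suite. The design-power check uses
1000 replicates of the 28-subject t-test comparison.

## Known limitations

- Timecourse degrees of freedom are (N_obs − rank); no
  Satterthwaite/Kenward-Roger. Slope CIs use the CR2 cluster-robust
  covariance with t(n_subjects − 1), which at 32 subjects still runs a
  shade anti-conservative for the series-2 slope (coverage ≈ 83-91% at
  nominal 90% across calibration batches; series 1 ≈ 87-94%).
- Subject-specific heart-rate-correction error interacting with the
  postprandial RR drop gives every subject a small apparent concentration
  slope of its own. The double difference cancels it within subject, so
  series-1 inference is calibrated; the series-2 time-factor model cannot,
  its trial-level slope errors are heavy-tailed, and its nominal 90% CIs
  are optimistic by a few percent. When the two series disagree on
  uncertainty, series 1 is the safer read at this design size.
- The random-intercept variants understate slope uncertainty when the
  response is heterogeneous between subjects; AIC correctly prefers the
  random-slope variants in that regime, matching the original analyses.
- Series-1 variant 3 (zero fixed intercept) sits on a variance boundary in
  null data and is the most fragile fit; the optimiser chain handles it but
  its REML AIC can be degenerate (reported as +inf, never selected).
- The linear QTcI attenuation of additive effects (~3-4%) is inherent to
  the correction form, not a defect of the estimator.
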
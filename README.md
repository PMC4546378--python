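# cqtkit

Concentration-QTc (C-QT) exposure-response analysis for crossover ECG
trials, with a meal-based assay-sensitivity test and a synthetic-trial
generator.

## Who this is for

Drug developers and biostatisticians running intensive-QT (IQT) analyses in
early-phase trials: studies with triplicate 12-lead ECGs at many time points,
time-matched PK sampling, and no pharmacological positive control. The
package implements the full analysis chain for a four-period
single-ascending-dose crossover (placebo and three active doses, a drug-free
baseline day per period, standardised meals at 5 and 9 h post-dose):

- **ECG processing** — triplicate median reduction; Fridericia correction
  QTcF = QT/RR^(1/3); individually fitted corrections (QTcI) chosen per
  subject between `QT = a + b·RR` and `ln QT = a + b·ln RR` by the smallest
  |corr(QTc, RR)|, then the smallest |slope|, then log-log; average-baseline
  changes ΔQTc and time-matched placebo-subtracted ΔΔQTc.
- **Per-time-point analysis** — `QtcTimecourseModel`: a linear mixed model
  ΔQTc ~ sequence + period + sex + treatment×time + baseline, random subject
  intercept (compound symmetry), dose-vs-placebo contrasts with 90% CIs and
  the largest time-matched difference per dose.
- **Concentration-effect models** — `ConcentrationQtModel`: series 1
  regresses ΔΔQTc on concentration (variants: random intercept, + random
  slope, or zero-fixed-intercept with random intercept and slope); series 2
  regresses ΔQTc on concentration with time as a factor using placebo rows
  at concentration 0, so the slope is corrected for the spontaneous time
  course. AIC selects the variant; the selected model predicts the QTc
  effect at each dose's geometric-mean Cmax with t-based or subject-bootstrap
  CIs.
- **Assay sensitivity** — the known postprandial QTc shortening after a
  standardised lunch, tested as the series-2 time contrasts at 6 and 8 h
  versus pre-dose with fixed 95% (Bonferroni) CIs: the assay is sensitive if
  both CIs are entirely below 0 and both point estimates are at or below
  −5 ms.
- **NCA** — Cmax, tmax, t½, AUC0-t/0-24/0-∞ by linear-up/log-down trapezoids
  and a best-adjusted-R² terminal λz fit, with dose-group summaries.
- **Synthetic trials** — a generator producing design, PK and triplicate ECG
  tables with the same statistical structure (one-compartment dose-
  proportional PK, per-subject QT-RR power laws, between-subject QTc SD
  ≈ 8 ms, postprandial shortening ≈ −8 ms, optional linear drug effect), so
  the whole pipeline is testable without clinical raw data.

## Worked example

```python
from cqtkit import (QtModelParams, simulate_trial, build_observations,
                    ConcentrationQtModel, nca_table, geometric_mean_cmax,
                    assay_sensitivity)

# a 32-subject crossover with a QTc-shortening drug effect of
# -0.0008 ms per ng/mL
design, pk, ecg = simulate_trial(32, seed=1,
                                 qt_params=QtModelParams(drug_slope=-0.0008))
obs, corrections = build_observations(ecg, pk, design.subjects_frame())

fit = ConcentrationQtModel(obs, series=2, variant=1, qtc_variable="qtci").fit()
print(fit.summary())

cmax = geometric_mean_cmax(nca_table(pk), "500 mg")
pred = fit.predict_at(cmax, dose_group="500 mg")
print(f"predicted effect at {cmax:.0f} ng/mL: "
      f"{pred.point:.1f} ms (90% CI {pred.ci_low:.1f}, {pred.ci_high:.1f})")

results, met = assay_sensitivity(obs)  # QTcF, times 6 and 8 h
for r in results:
    print(f"{r.time_h:.0f} h: {r.estimate_ms:.1f} ms "
          f"(95% CI {r.ci_low:.1f}, {r.ci_high:.1f})")
print("assay sensitivity criterion met:", met)
```

prints (seed 1):

```
Concentration-QTCI mixed model (series 2, variant 1, analyte parent)
observations: 2432
slope: -0.00074 ms/(ng/mL)  90% CI [-0.00084, -0.00063]
fixed intercept: 1.557 ms
AIC (restricted): 14135.8
predicted effect at 3754 ng/mL: -2.8 ms (90% CI -3.2, -2.4)
6 h: -6.9 ms (95% CI -8.0, -5.7)
8 h: -6.1 ms (95% CI -7.3, -5.0)
assay sensitivity criterion met: True
```

The fitted slope recovers the injected −0.0008 ms/(ng/mL) (the individually
corrected QTcI endpoint carries a small structural attenuation; see
`docs/methods.md`). The postprandial contrasts recover the injected meal
effect (−8 ms decaying with a 16 h time constant gives −7.5/−6.6 ms at
6/8 h) and both sit below −5 ms with CIs below 0, so the simulated assay
would have detected a small QTc change.

The same pipeline runs from the shell:

```bash
cqtkit simulate --n 32 --seed 1 --out trial/
cqtkit all --seed 1 --out results/        # simulate + process + fit + report
cqtkit all --seed 1 --in trial/ --out results/   # or from existing CSVs
```

writing `qtc_observations.csv`, `timecourse_contrasts.csv`,
`model_fits.csv`, `predictions.csv`, `assay_sensitivity.csv`,
`nca_results.csv`/`nca_summary.csv` and a `summary.json` digest.

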
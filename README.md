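# poaf-twin

A digital-twin simulation pipeline for **postoperative atrial fibrillation
(POAF)** after cardiac surgery. POAF affects roughly a quarter of cardiac
surgery patients within the first postoperative week; static risk scores
(CHA₂DS₂-VASc, HAS-BLED, STS) discriminate poorly and give no handle for
*when* or *in whom* to intervene. This package implements, end to end and
fully in silico, the alternative: patient-specific electrophysiology
"twins" calibrated to ECG features, synthetic-cohort generation, and
virtual randomized controlled trials of a twin-guided prophylaxis policy.

It is written for methodologists in biostatistics / computational
cardiology who want a tested, reproducible sandbox in which every stage —
from the ionic model to the log-rank test — is open, seeded and checked
against independent oracles.

## What it computes

**Ground-truth cohort.** `synth_cohort` generates perioperative patients
(demographics, comorbidity flags, PR/QRS/QT intervals, RR, HRV SDNN,
K⁺/Mg²⁺, CRP, BNP) through a Gaussian copula with documented correlation
structure, and draws a 7-day POAF outcome from a discrete-time hazard

  logit h_d = logit(h₀) + β_v z_vuln + β_e z_elec + β_i z_infl + β_a z_age,

scaled by a day-shape profile and calibrated so the untreated 7-day
cumulative incidence is 27.6 %. Missingness (<5 %, MCAR) is injected and
removed by chained-equations regression imputation.

**Electrophysiology twin.** `cell_ep` is a six-current Hodgkin-Huxley
atrial myocyte (I_Na, I_CaL, I_Kr, I_Ks, I_K1, leak; RK4, dt = 0.02 ms)
with baseline APD90 ≈ 282 ms and V_rest ≈ −80 mV at 1 Hz. `tissue_ep`
propagates it on 1-D fibers (monodomain operator splitting, plus a
bidomain solver equivalence-checked against the equal-anisotropy
reduction). `twin_builder` calibrates the I_Kr scale per patient so that
APD90 + offset matches the Bazett QTc, then summarizes the twin as a
vulnerability index (APD prolongation, CV slowing, dispersion,
electrolyte deficit, inflammation).

**Virtual RCT.** `virtual_trial` allocates the cohort 1:1, treats
intervention-arm patients above the twin-probability threshold
(electrolyte repletion to K > 4.0 / Mg > 2.0 mEq/L plus an antiarrhythmic
hazard multiplier whose effect is maximal when started 48–72 h before
surgery), simulates daily events over 7 days, and reports incidences,
relative risk reduction, LOS/ICU/stroke outcomes, Kaplan-Meier curves and
the log-rank test — all implemented in-module and oracle-tested.

**GAN cohorts and metrics.** `gan_cohort` trains a compact numpy
generator/discriminator pair on the covariate table and validates
synthetic cohorts with per-feature Kolmogorov-Smirnov statistics and a
correlation-gap criterion against a Gaussian-copula baseline.
`evaluation` provides Mann-Whitney AUC with stratified bootstrap CIs,
Youden thresholds, Wilson intervals, Hosmer-Lemeshow, calibration slope
(in-module IRLS) and the Brier score.

## Worked example

```python
from poaf_twin.synth_cohort import GroundTruthConfig, generate_cohort
from poaf_twin.twin_builder import build_twins
from poaf_twin.risk_models import score_panel
from poaf_twin.virtual_trial import TrialConfig, simulate_trial

gt = GroundTruthConfig()
cohort = generate_cohort(gt, n=10_000, seed=11)
twins = build_twins(cohort)                 # caches APD90 over an s_Kr grid
panel = score_panel(cohort, twins)
report = simulate_trial(cohort, panel["twin_prob"], gt, TrialConfig(seed=11))
print(report.text_table())
```

```
outcome                 intervention     control           p
POAF incidence                18.6%      27.6%     1.6e-26
relative risk red.            32.6%
mean LOS (days)                  7.4         7.9       3e-13
mean ICU (days)                  2.2         2.5     6.6e-20
stroke incidence               1.6%       1.8%        0.36
log-rank p                   2.3e-27
```

Reading: the control arm reproduces the configured 27.6 % untreated
incidence; the twin-guided policy (treating the top 40 % by twin
probability, optimally timed) lowers it to ≈18.6 %, a ≈33 % relative risk
reduction, with correspondingly shorter stays and a stroke trend. The
same objects expose the KM curves, per-arm summaries and all test
statistics programmatically.

A CLI mirrors the stages (`poaf-twin run|generate|calibrate|gan|trial|
sweep|evaluate|report --seed 1 --out artifacts`).

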
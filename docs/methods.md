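# Methods

This note documents the models, the parameter choices that matter, the
numerical decisions, and what the synthetic study design does and does
not establish.

## Synthetic cohort and the ground-truth POAF mechanism

The generator emulates the covariate table of a perioperative cardiac
surgery registry. Continuous features are drawn through a Gaussian
copula: a latent multivariate normal with a fixed correlation matrix
(age–QTc +0.20, age–HRV −0.30, K–Mg +0.30, CRP–BNP +0.30, etc., all
listed in `synth_cohort._pairs`) mapped through clipped-normal or
log-normal marginals. Key marginals and the reasons for them:

| feature | marginal | rationale |
|---|---|---|
| age | N(66, 10) clipped ≥18, ≤95 | typical cardiac-surgery population |
| QTc | N(420, 30) ms, [350, 520] | realistic Bazett-corrected QT |
| RR | N(0.90, 0.12) s | resting heart rate ~55–90 bpm |
| HRV SDNN | N(60, 15) ms (log-encoded for the GAN) | short-term SDNN range |
| K⁺ | N(4.1, 0.45) mEq/L, [2.8, 5.8] | perioperative serum potassium |
| Mg²⁺ | N(2.0, 0.25) mEq/L | serum magnesium around the 2.0 target |
| CRP | logN(ln 5, 0.8) mg/L | right-skewed inflammatory marker |
| BNP | logN(ln 150, 0.9) pg/mL | right-skewed natriuretic peptide |

QT is stored as QTc·√RR so the `qt_ms < rr_s·1000` invariant holds by
construction. Comorbidity flags are Bernoulli with age-dependent logits.

The outcome is a discrete-time daily Bernoulli hazard over 7 days,
logistic-linear in four standardized composites: repolarization
vulnerability (0.6·QTc-z + 0.4·HRV-depression-z), electrolyte deficit
below the 4.0/2.0 mEq/L targets, inflammation (CRP with a 0.3-weighted
BNP term), and age. Coefficients default to (0.7, 0.5, 0.35, 0.3); a
day-shape profile peaks on postoperative day 2. The baseline daily
hazard (0.0275681) is the root of the population-mean 7-day cumulative
incidence equation at the 27.6 % target, computed once by
`calibrate_baseline_hazard` and shipped as the default. The mechanism is
deliberately closed-form in the record (it does not run the ODE model),
so every downstream stage has a cheap, recoverable ground truth.

The preoperative timing profile `benefit_profile` is piecewise linear
with knots (0 h → 1.0, 48 h → 0.6, 72 h → 0.6, 120 h → 1.0): it is the
treated-hazard multiplier of a *fully effective* drug as a function of
lead time, encoding maximal benefit 48–72 h before surgery as ground
truth so the window sweep has a known optimum.

Missingness is injected completely at random in eight lab/ECG columns at
3 % by default (a warning is raised at ≥5 %); `rr_s` and `age` stay
complete so heart-rate correction is always defined. Chained imputation
regresses each incomplete column on all other continuous columns (OLS),
cycling until the largest imputed-value change is below `tol` in units of
the column SD (default 10 sweeps, tol 1e-6). A single completion is
returned by default; `m > 1` adds residual-scale Gaussian noise per
completion.

## Atrial cell model

A minimal six-current Hodgkin-Huxley-formalism atrial myocyte: fast
sodium (m³h), L-type calcium (d·f, slow inactivation τ_f = 260 ms),
rapid and slow delayed rectifiers (x_r, x_s²), an inward rectifier with
voltage-dependent block, and a depolarizing background leak
(E_leak = −30 mV) that balances I_K1 so the rest potential sits at
−79.7 mV. Conductances (g_CaL = 0.50, g_Kr = 0.08, g_Ks = 0.12,
g_K1 = 0.22, g_leak = 0.028 mS/cm²) were tuned once so that at 1 Hz
pacing the baseline APD90 is 281.8 ms, inside the 250–320 ms atrial
band, with APD90 strictly decreasing in the s_Kr and s_Ks scales and
increasing in s_CaL over [0.5, 1.5] — the property the per-patient
calibration relies on. Integration is explicit RK4 at dt = 0.02 ms
(halving dt moves APD90 by <0.01 ms); Rush-Larsen is available and
agrees within 2 ms. The stimulus is a 2 ms rectangular pulse; a
bisection helper finds the diastolic threshold.

Over s_Kr ∈ [0.5, 1.5] the model spans APD90 ≈ 224–358 ms, i.e. QTc
targets of ≈364–498 ms under the QT mapping below; cohort QTc values
outside that range saturate at a bound and are flagged non-converged
(~2 % of patients at defaults).

## Tissue propagation

The operational solver is the 1-D monodomain equation with operator
splitting (RK4 reaction per node, explicit finite-difference diffusion,
no-flux mirrored boundaries) under an enforced dt ≤ dx²/(2D) stability
bound. Defaults: 100 nodes, dx = 0.25 mm, D = 0.1 mm²/ms, giving
CV = 0.51 mm/ms — inside the 0.3–1.2 mm/ms atrial benchmark band — and
CV scaling as √D within 10 % over a 4× range, as cable theory predicts.
Conduction velocity is measured over the central 60 % of the fiber to
avoid boundary effects; repolarization dispersion is max−min APD90 over
the same band.

The bidomain variant solves the elliptic extracellular-potential
constraint each step by a pre-factored tridiagonal (Thomas) solve with
the gauge fixed at node 0. With proportional conductivities it reduces
exactly to monodomain at the harmonic-mean diffusion; the test suite
verifies activation times match within 1 ms on a 50-node fiber.

## Twin calibration and the vulnerability index

Per patient, the Bazett-corrected QT (QTc = QT/√RR) is mapped to a
target APD90 by a fixed offset: **QTc ≈ APD90 + 140 ms**. The offset is
chosen so the population-mean QTc (420 ms) maps onto the baseline APD90
(282 ms): atrial APD90 is substantially shorter than the ventricular
repolarization the surface QT measures, and a 60-ms "activation only"
offset would place almost the entire cohort beyond the reachable APD
band and saturate the calibration at its bounds. The mapping is the
simplest invertible link; the exponent of the heart-rate correction is
configurable.

With one scalar target the three-conductance inverse problem is
under-determined, so the default frees s_Kr only (bounds [0.5, 1.5],
tolerance 2 ms, bounded scalar minimization, ≤200 evaluations, identity
start, with an identity-fallback guard so the returned objective never
exceeds the (1,1,1) start). A multi-parameter Nelder-Mead mode exists
and is always flagged `underdetermined`.

Because a fresh ODE solve per objective evaluation would make 10,000
calibrations take hours, the forward map s_Kr → APD90 is evaluated once
on a 17-point grid (full RK4 runs) and interpolated with a monotone
PCHIP spline; a companion cache interpolates fiber CV and the dispersion
of a half-baseline/half-patient fiber over a 5-point grid. Interpolation
error is <0.5 ms, far below the 2 ms tolerance, and is tested against
off-grid ODE runs. Single-record parameter recovery over ODE-generated
targets has median |ŝ_Kr − s_Kr| ≪ 0.05.

The vulnerability index is logistic(w·z) over five standardized
components: APD prolongation ((APD−281.8)/30), CV slowing
((0.51−CV)/0.1), dispersion (/10 ms), electrolyte deficit below the
4.0/2.0 targets, and log-CRP inflammation; default weights (1.0, 0.5,
0.5, 0.7, 0.5). Degenerate components standardize to 0. The twin POAF
probability is logistic in the index plus age/CHF/hypertension terms.
On default cohorts it reaches AUC ≈ 0.73–0.74 versus ≈ 0.59 for
CHA₂DS₂-VASc and 0.76–0.77 for the (unobservable) true risk — the twin
recovers most of the mechanism's signal through the QTc and lab
channels while the additive scores see only age and flags.

## Virtual trial

1:1 allocation by seeded permutation (odd cohorts are rejected
explicitly). Intervention-arm patients above the policy threshold (60th
percentile of twin probability by default, i.e. 40 % treated) receive:

* electrolyte repletion — K and Mg raised to max(current, target),
  which lowers the ground-truth hazard mechanistically; and
* an antiarrhythmic effect — the daily hazard is multiplied by
  `m_eff = hm + (1 − hm)·benefit(lead_time)`, the convex combination of
  the drug multiplier `hm` and no effect. The profile is the multiplier
  of a fully effective drug (hm = 0), `hm = 1` is exactly null at any
  lead time, and under the default profile the optimal window realizes
  `m_eff = 0.6 + 0.4·hm`.

The default `hm = 0.1` (realized multiplier 0.64 in the window) is an
explicit calibration: it was chosen, before the acceptance tests were
frozen, as the value for which the default end-to-end trial at n =
10,000 yields a mean relative risk reduction of ≈34 % across seeds.
Notably, electrolyte repletion alone (hm = 1) already produces ≈18 %
RRR under this mechanism because treatment is targeted partly *by*
electrolyte deficit.

Secondary outcomes: LOS = (6.5 + 5·I(POAF)) days and ICU =
(1.8 + 2.5·I(POAF)) days, each with unit-mean multiplicative lognormal
noise (σ = 0.3/0.4); stroke Bernoulli at 0.8 %/4 % without/with POAF.
Arms are compared with the pooled two-proportion z-test (POAF, stroke),
Welch's t-test (LOS, ICU), and POAF-free survival via the in-module
product-limit estimator and log-rank test (both cross-checked against
`lifelines` and hand-worked examples). The lead-time sweep re-runs the
trial at fixed seed over a grid of lead times and reports the argmin.

## GAN cohorts and fidelity

Generator and discriminator are two-hidden-layer (64, 64) perceptrons in
numpy with explicit backpropagation and Adam (lr 1e-3, β₁ 0.5), latent
dimension 16, batch 128 — training is exactly reproducible under a seed.
Mixed types: continuous features standardized (CRP, BNP, HRV on the log
scale), flags as Bernoulli probabilities, sex/surgery as softmax blocks.
During training the generator's discrete outputs are *sampled to hard
values* with straight-through gradients; without this the discriminator
separates real (hard 0/1) from fake (soft) rows trivially and the
continuous features never converge. Cosine learning-rate decay and an
EMA (0.999) of generator weights stabilize the endpoint. Outcome columns
are never generated adversarially: POAF is re-simulated from the
ground-truth hazard on generated covariates, keeping the trial's event
mechanism explicit.

Fidelity: two-sample KS per continuous feature (pass < 0.1),
total-variation distance of category frequencies (pass < 0.05), and the
Frobenius norm of the continuous correlation-matrix difference (pass
< 0.5). At 300 epochs on a 5,000-row cohort the trained GAN reaches
max KS ≈ 0.03 and correlation gap ≈ 0.32–0.35.

A note on the copula comparison: the Gaussian-copula baseline estimates
its correlation matrix *from the comparison sample itself*, so its
correlation gap (~0.13 at n = 5,000) is systematically below what any
independent sampler can achieve — an independent draw from the true
generator measures 0.15–0.20. The regression test therefore bounds the
GAN by 1.5× the larger of the copula gap and the median of three
independent-draw noise floors, which preserves the "within 1.5× of the
attainable reference" intent without demanding a statistically
impossible number.

## Evaluation metrics

AUC is the Mann-Whitney concordance probability with average-rank tie
handling (exact against an O(n²) pair-counting oracle and
scikit-learn); CIs by class-stratified percentile bootstrap (2,000
resamples). Youden's J picks the operating threshold, ties broken toward
higher specificity; Wilson intervals for the 2×2 ratios. The
Hosmer-Lemeshow statistic uses deciles of risk with χ²(g−2) — the
reference distribution appropriate when the probabilities come from a
fitted model, which is how the null-uniformity test constructs them;
degenerate groups are merged and logged. The calibration slope comes
from an in-module IRLS logistic fit of outcomes on logit(p)
(cross-checked against statsmodels); separation raises rather than
returning a spurious slope.

## Problem sizes and determinism

Default study sizes: cohort 10,000; GAN trained on 5,000 rows for 300
epochs (600 in the regression test); lead-time grid {12, 24, 48, 60, 72,
96, 120} h; null-trial calibration 200 seeds at n = 200. Every
stochastic stage takes a seed derived from the global seed by hashing
the stage name; the ODE kernels are numba-compiled and bitwise
deterministic.

## Limitations

* The ground-truth outcome mechanism is a modelling convenience: it is
  logistic-linear with MCAR missingness and no unmeasured confounding,
  so passing tests demonstrate internal consistency of the pipeline, not
  performance on real registries (which also exhibit informative
  missingness, measurement error, site effects and exclusion cascades).
* The cell model is a minimal formalism carrier, not a physiological
  atrial model: no intracellular calcium handling, no rate-dependent APD
  restitution beyond gate kinetics, and the QTc→APD offset is a fixed
  population constant rather than a per-patient quantity.
* The twin's CV component barely varies across patients (s_Kr has little
  effect on upstroke velocity), so discrimination is carried mainly by
  the APD/dispersion and laboratory channels.
* Arm-level LOS/ICU gaps follow from the configured outcome constants
  (5- and 2.5-day POAF penalties), which produce smaller absolute
  between-arm differences than a registry with longer POAF-attributable
  stays would show.
* GAN training at desk scale trades capacity for runtime; the fidelity
  suite checks marginals, category frequencies and second moments, not
  higher-order interactions.
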
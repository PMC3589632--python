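# Methods

## The model

`civipop` analyses sparse plasma-concentration data from a drug given as a
7-day (168-h) constant-rate intravenous infusion repeated every 21 days.
The structural model is a linear one-compartment model parameterised by
total body clearance CL (L/h) and apparent volume of distribution V (L),
with the closed form

    C(t) = (R/CL) (1 - e^{-k(t - t0)})          t0 <= t <= t0 + D
    C(t) = C(t0 + D) e^{-k(t - t0 - D)}         t > t0 + D,   k = CL/V,

superposed over dose cycles.  Predictions are computed analytically, never
by ODE integration (an ODE integrator serves as an independent oracle in the
test suite only).  A query time exactly at the infusion stop uses the
during-infusion branch; the two branches agree there, so this is purely a
tie-break convention.  Units are fixed package-wide: hours, mg, L, ng/mL,
with the single mg/L → ng/mL factor of 1000 applied at the prediction
boundary.

Between-patient variability is a single log-normal random effect on
clearance, `CL_i = TVCL_i * exp(eta_i)` with `eta ~ N(0, omega2)`; V carries
no random effect.  Sparse 7-day-infusion data identify V only weakly (most
samples sit at plateau, which depends on CL alone), and a previous
two-compartment attempt on such data was abandoned for this reason; the
post-infusion samples in cycle 1 are what identify V here.

Typical clearance is a multiplicative covariate model,

    TVCL_j = CL_pop * prod (X_j/X_ref)^theta_power * prod theta_ratio^{Z_j},

with power terms for continuous covariates (creatinine clearance normalised
to 79.22 mL/min and ALT to 19.0 U/L — fixed reference values near the
population medians of the motivating cohort; other covariates use the
dataset median) and ratio terms for 0/1 indicators (cancer type enters as a
2-degree-of-freedom block of two indicators against the NSCLC reference).

Residual error is proportional, `C_obs = C_pred (1 + eps)`, with two
variances: `sigma2_normal` for ordinary patients and a larger
`sigma2_outlier` for patients flagged as carrying possible outlier
concentrations.  Flagging uses Tukey-style fences on the pooled
during-infusion concentrations: strictly outside `[Q1 - 3 IQR, Q3 + 3 IQR]`
with quartiles by linear interpolation between order statistics (the
"type 7" rule, the most widespread default; the estimator is configurable).
Flagged observations are retained — the two-variance model absorbs them —
and the whole patient moves to the wide error group (an observation-level
alternative exists but is off by default).  Pooling across patients and
cycles (rather than per patient) is the default because a single global
fence is what a three-study pooled analysis reports; a per-patient mode is
available.

Creatinine clearance is derived at load time by Cockcroft–Gault,
`(140 - age) * weight / (72 * Scr[mg/dL])`, times 0.85 for women; serum
creatinine arrives in umol/L and is converted with 88.4 umol/L per mg/dL.

## Estimation

The marginal likelihood is approximated per patient by a Laplace expansion
around the conditional mode of eta, with the residual variance evaluated at
that mode — the "interaction" convention.  For this single-random-effect
model this is functionally the FOCE-I family; exact numerical equality with
any particular NONMEM build is not a goal, only OFV-difference behaviour and
parameter recovery.  All additive constants (2-pi terms) are retained, so
the objective is directly comparable with exact quadrature, and OFV
differences between nested models are likelihood-ratio statistics.  At
`omega2 = 0` the expression collapses analytically to the exact pooled
Gaussian likelihood.

The inner problem (the conditional eta mode) is a vectorised safeguarded
Newton iteration over all patients simultaneously, using central-difference
derivatives of the 1-D conditional objective; the gradient tolerance is
1e-8, chosen just above the finite-difference noise floor, which still
locates each mode to about 1e-9.  The curvature entering the Laplace term
uses a central difference with step 1e-4, floored at a small positive value.

The outer problem runs BFGS with numerical gradients (step 1e-5) on
transformed parameters: log for CL, V, omega2 and both sigma2; log for
ratio coefficients; raw for power exponents.  Convergence requires either
the optimiser's own success flag or a residual gradient below 0.5 OFV units
(BFGS routinely stops with a "precision loss" message at the
finite-difference noise floor; the corresponding parameter error is far
below reporting precision).  Non-finite objective values are mapped to a
large finite constant so the optimiser can back out of overflow regions.
When a dataset contains no observations in the wide error group,
`sigma2_outlier` is held at its starting value and excluded from the search
and from standard-error reporting.  Default starting values are CL 40 L/h,
V 300 L, omega2 0.1, sigma2 0.1, powers 0, ratios 1.

Standard errors come from the central-difference Hessian (step 1e-4) of the
objective at the optimum; the covariance is `2 H^{-1}` (the objective is
-2 log L) and is reported as CV% — for log-scale parameters the transformed
SE is itself the approximate CV.

Empirical-Bayes ("post-hoc") estimates are the conditional eta modes at the
fixed population estimates; patients with no analysable observations get
eta = 0 with a zero observation count.  Diagnostics report PRED (eta = 0),
IPRED (conditional eta) and classic population WRES: each patient's
residual vector whitened by the Cholesky factor of the first-order
covariance `omega2 G G' + diag(sigma2 PRED^2)`, `G = dPRED/deta` at zero.
Conditional WRES variants are deliberately out of scope; the dialect choice
is documented here.

## Covariate selection

Screening regresses the base-model etas on each continuous covariate
(simple linear regression) and compares groups for categorical covariates
(t-test, or one-way ANOVA above two levels) at a default alpha of 0.1 —
the screening threshold of the motivating analysis is not recorded, so this
is a declared choice, not a reconstruction.  Forward addition refits the
current model with each surviving candidate block and adds the block with
the largest significant OFV drop (chi-square, df = parameters added; 3.84
for 1 df, 5.99 for the 2-df cancer-type block at alpha 0.05), repeating
until nothing qualifies; backward elimination then removes, one at a time,
the block whose exclusion raises OFV least whenever that rise is not
significant at alpha 0.01 (6.63 / 9.21).  Ties in the drop are broken by
candidate list order.  No small-sample correction is applied to the
likelihood-ratio p-values, matching standard pharmacometric practice.
Candidate fits that fail are skipped for that round and logged.

## Bootstrap

Validation resamples whole patients with replacement to the original count,
refits with the point estimates as starting values, and reports 2.5th /
97.5th percentile intervals (linear interpolation, the same rule as the
quartile estimator) over converged replicates only; failures are counted.
Resampling is stratified by study by default so both cancer-type indicator
columns stay non-degenerate in every replicate; an unstratified mode mirrors
the plain "sample patients with replacement" reading.

## Exposure

Steady-state concentration per cycle is `Css = Dose / (CL * 168 h) * 1000`
with the dose read as the total mg infused in one cycle (4.8 mg/m2/day x
BSA x 7 d) and CL the individual post-hoc estimate.  Because Css is
inversely proportional to CL, a covariate's CL ratio maps to the reciprocal
Css ratio; the renal-effect summary tabulates both as percent changes
against the 79.22 mL/min reference.  Exposure-safety analysis is limited to
exporting per-patient Css for external grouping; no statistics are computed.

## The virtual-study generator

The generator reproduces the pooled three-study design: 33 + 34 + 29
patients, 4.8 mg/m2/day for 168 h every 504 h, and about six samples per
patient — during-infusion draws at 24, 96 and 168 h of cycle 1 (the last
immediately before the stop), one draw in each of the 0.5–4 h and 6–24 h
post-stop windows of cycle 1, and one during-infusion draw (at 72 h) in
cycle 2.  Sampling times beyond cycle 1 are a declared default, not a
reconstruction — the source design records them only as "during the
infusion".  Two cycles are simulated by default.

Covariate marginals are truncated distributions matched to the cohort
screening table: normal for age (mean 63, SD 11.7, range 29–90), weight
(82, 14.3, 50–114) and height; log-normal for the right-skewed laboratory
values (serum creatinine median 88 umol/L, log-SD 0.26; ALT median 20 U/L,
log-SD 0.78, chosen to reproduce the published mean/median ratio; AST;
alpha1-acid glycoprotein).  BSA follows from weight and height by the
Mosteller formula (clipped to the observed 1.48–2.40 m2 range), and CLCR by
Cockcroft–Gault, so body size, age and renal function carry their natural
correlations.  All HRPC patients are male; the other studies draw females
at the pooled 17/62 rate.  Covariates are otherwise independent, which is
the main respect in which the generator is simpler than real data — passing
recovery tests demonstrates estimator correctness under the stated model,
not robustness to real-world covariate collinearity or model
misspecification.

True parameters default to the final-model estimates (CL 42.1 L/h, V 319 L,
CLCR power 0.425, ALT power 0.124, HRPC ratio 0.955, MM ratio 1.24, omega2
0.0385, sigma2 0.0934).  About 11% of patients can be "contaminated":
their noise uses the wide variance (default CV 100% — the published scale
of the wide-group estimate is ambiguous, so this is a declared generating
choice) and one or two of their during-infusion samples are multiplied by a
uniform 5–50x spike.  The spike mechanism is synthetic fiction: the original
fluctuations had no identified cause, but an injected ground truth is what
lets the flagging rule be tested exactly.  Concentrations below the
0.05 ng/mL quantitation limit are marked BLQ and excluded from analysis
(never imputed).

## Problem sizes used in the checks

Parameter-recovery runs use the full 96-patient design over 5 seeds.
Selection-calibration uses 200 null replicates of 40 patients with a single
1-df candidate; interval-coverage uses 10 meta-replicates of 30 patients
with 50 bootstrap resamples each.  These sizes give binomial/Monte-Carlo
error small enough for the stated bands while keeping a full run of the
suite inexpensive.

## Known limitations

- One compartment, one random effect, proportional error only; no
  inter-occasion variability, no BLQ likelihood handling (M3), no
  covariates on V.
- The Laplace/FOCE-I objective is approximate; agreement with adaptive
  Gauss–Hermite quadrature is verified to <=0.5 OFV units on small
  instances, and the approximation error shrinks with omega2.
- Bootstrap intervals are plain percentile (no BCa / bootstrap-t).
- The generator draws covariates independently (see above) and its
  contamination mechanism is invented.
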
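# Methods

## Problem

Sarcopenia screening in dialysis patients relies on cut-off values of
handgrip strength (HGS, kg) and lean mass index (LMI, kg/m²) taken from
general-population guidelines.  This package implements the alternative,
prognostic route: derive the cut-offs from the exposure–mortality
relationship in a peritoneal-dialysis (PD) cohort itself, then check on a
held-out part of the cohort whether patients below the derived thresholds
really die at a higher rate and how well a model built on the dichotomized
exposure predicts individual vital status.

No patient-level data accompany the published cohort the design follows, so
a synthetic-cohort generator with the published aggregate structure serves
as the test bed; every statistical component is exercised against ground
truths the generator controls.

## Body composition

Lean body mass is estimated from anthropometry with a linear equation for
CKD stage 3–5 patients:

    LBM (kg) = 4.72·[male] + 0.28·height_cm + 0.27·weight_kg
               + 0.02·HGS_N − 0.04·vintage_months − 26.84

Dynamometers report kg of force while the equation takes Newtons; the kg
reading is multiplied by standard gravity (9.80665 N/kg) exactly once.  LMI
is LBM/height².  The equation is linear and unbounded; physiologically
absurd inputs can drive it negative, which is returned as-is with a warning
since the equation defines no floor.  Baseline exposures are means over the
first 3 months on dialysis (`baseline_average`); the cohort table carries
one baseline value per patient, and per-hand measurement averaging is
treated as upstream of this package.

## Synthetic cohorts

`SimulationParams` defaults encode the published development-cohort
aggregates: 50.8% male, 38.9% diabetic, 39.5% with cardiovascular disease,
age 56.5 ± 15.2 y (truncated to 18–95), albumin 35.6 ± 4.6 g/L, and
sex-conditional anthropometry chosen to reproduce the pooled moments
(HGS ≈ 22.0 ± 10.9 kg, LMI ≈ 15.6 ± 1.9 kg/m², height 164.3 ± 8.5 cm): only
pooled values are published, but sex-specific cut-offs require a sex gap, so
male/female HGS means of 29/15 kg (SD 8) and LMI 16.6/14.6 (SD 1.5) are
used.  Covariates are independent given sex; the published tables contain no
correlation structure to copy.

Outcomes follow a competing-risks model with independent exponential latent
times per cause — death, transfer to hemodialysis (4.3/100 person-years),
transplantation (3.1), loss to follow-up (0.7) — plus administrative
censoring at 120 months (yielding a follow-up median near the published
36–44 months).  Constant cause-specific hazards are the minimal model
consistent with the published constant per-100-person-year event rates.  The
death hazard is either

* **proportional**: log-linear in age (0.039/y), DM (0.395), CVD (0.454),
  albumin (−0.002 per g/L) and one exposure (HGS −0.027/kg or LMI
  −0.093 per kg/m²), the published adjusted coefficients, centred at the
  population means; or
* **step**: baseline × `hr_below` when the exposure is below a sex-specific
  threshold (defaults 24.5/14.0 kg HGS, HR 2) — a known-truth scenario for
  cut-off recovery studies.

In both modes the baseline hazard is calibrated by root-finding on the
realised covariates so the expected marginal death rate matches the target
(11.1/100 person-years), using the closed-form expectations of the
competing-exponentials model.  All draws flow from a single seed through
named substreams; identical parameters give byte-identical CSV output.

What the generator does **not** emulate: staggered study entry (censoring is
a fixed horizon, not calendar-driven), longitudinal exposure trajectories,
covariate correlations beyond sex, non-exponential hazards, and the
real cohort's unknown measurement error.  Passing recovery tests therefore
demonstrate correctness of the estimation machinery under the stated model,
not robustness to real-data violations of it.

## Cohort operations

The development/validation split is random within the four sex × diabetes
strata, with the development count per stratum equal to round-half-up of
70% of the stratum size — matching proportions deterministically while
randomising membership.  Descriptive comparisons use the t test (normal
continuous), Wilcoxon rank-sum (skewed) or Pearson chi-square without
continuity correction (categorical).  Event rates are `100 × events /
person-years` with person-time summed over the whole cohort per cause.
Records missing a model covariate are excluded from model fits with a
logged count; no imputation is attempted.

## Spline Cox model and cut-off derivation

The exposure enters a cause-specific Cox model (death is the event; all
other causes censor) through a restricted cubic spline: four knots at the
20/40/60/80th percentiles of the fitting sex's exposure distribution give a
3-column natural-spline basis (linear tails beyond the outer knots, the
standard truncated-power construction scaled by the squared knot span).
Age, DM, CVD and albumin enter linearly.  Fitting is by partial-likelihood
maximisation via statsmodels' `PHReg` (Breslow ties by default, Efron by
flag); the covariance is the inverse observed information, and the Breslow
baseline cumulative hazard is computed right-continuously so a patient's
survival function includes the jump at their own event time.

The adjusted hazard-ratio curve is evaluated on a 0.1-unit grid over the
central 5–95% of the exposure (avoiding tail extrapolation), relative to the
sex-specific median; pointwise 95% bands come from the delta method on the
spline-block covariance.  HR(reference) = 1 exactly.

**Cut-off rule.**  Two read-outs are implemented; both first require the
lower 95% bound to exceed 1 somewhere (otherwise: no cut-off).

* `half_height` (default): the exposure at which the fitted log-HR first
  falls below half its low-exposure plateau (mean log-HR over the lowest
  10% of the grid).  For a threshold-like risk profile the spline smooths
  the step over roughly one inter-knot spacing, and the half-height
  crossing sits at the middle of that transition — an estimate of the
  threshold location whose error shrinks with sample size (median absolute
  error ≈ 1.9 → 0.9 kg for men over n = 500 → 5000 in the step scenario).
* `significance`: the point where the pointwise lower bound stops
  exceeding 1, scanning upward.  Because HR(reference) = 1 exactly, this
  read-out cannot exceed the reference and drifts toward it as power grows
  (at n = 3000 it lands near the male median, ~4.5 kg above a 24.5-kg
  truth).  It is retained because "where does significantly elevated risk
  end" is the natural clinical phrasing, but it should be read as a lower
  bound on where risk is elevated, not as a threshold-location estimate.

A sex stratum with fewer than 30 deaths yields a null cut-off with a
warning.  Derivation is deterministic given the cohort and grid step.

Competing events are handled cause-specifically throughout (competing
events censor the death hazard), consistent with the generator's
independent-latent-times model; a subdistribution-hazard (Fine–Gray)
analysis is not implemented.

## Validation and agreement

Patients are labelled low when the exposure is strictly below the
sex-specific cut-off (the reference group is ≥ cut-off).  Low-vs-high and
four-group (HGS × LMI) Cox models are fitted unadjusted (Model 1) and
adjusted (Model 2).  Note that dichotomizing at *estimated* cut-offs
misclassifies patients between the estimate and the truth, attenuating the
low-vs-high HR toward 1 relative to the generating value.

Outcome classification evaluates each patient's fitted survival function at
their own follow-up time, Ŝᵢ(tᵢ) = exp(−Λ₀(tᵢ)·e^{xᵢβ}), predicting death
when Ŝᵢ(tᵢ) ≤ 0.5 (threshold configurable).  Agreement is the percentage of
patients whose predicted status matches the observed death/non-death status
(all non-death causes count as non-death); chance-corrected agreement is
Cohen's kappa with the Fleiss–Cohen–Everitt asymptotic standard error for
its Wald 95% CI.

A caveat the synthetic experiments make explicit: because Ŝ(t) decreases in
t, the classify-at-own-time rule predicts death preferentially for patients
with *long* follow-up — who are disproportionately the censored survivors.
Under the generator's heavy administrative censoring the absolute agreement
sits near 40%, below chance, for every cut-off set.  The absolute level is
thus a property of the censoring pattern, not of the cut-offs; only
comparisons *between* sets on the same cohort are informative, and in the
step-hazard scenario the true cut-off set does score at or above ±5 kg
mis-placed sets in ~90% of pairwise comparisons.  Guideline HGS sets built
in for comparison: EWGSOP 2010 (30/20 kg M/F), EWGSOP 2019 (27/16), AWGS
(26/18), FNIH (26/16).

## Numerical choices

* Ties: Breslow default (Efron available); the Breslow baseline estimator
  is used for survival prediction under both.
* Convergence: a fit whose standardised coefficient magnitude exceeds 50,
  or with non-finite covariance, raises a convergence error naming the
  offending column (monotone-likelihood guard).
* Grid step 0.1 exposure units, matching the precision at which cut-offs
  are reported clinically.
* Wald CIs use z = 1.959963984540054 throughout.
* Split rounding: round-half-up per stratum; degenerate strata (empty) are
  allowed.
* Kappa with degenerate chance agreement (p_e = 1) is NaN; the agreement
  rate is still reported.

## Problem sizes

Default experiment sizes were chosen so every study runs comfortably on a
single CPU: recovery studies use cohorts of 500–5000 patients and 25–200
replicates; large-sample checks (event rates, coefficient recovery) use
20 000 patients.  The acceptance script reports medians over 25 replicate
cohorts for cut-off recovery and 10 for validation summaries.

## Known limitations

* The cut-off selection rule is not uniquely determined by the clinical
  problem; both implemented rules are documented choices, and the
  half-height rule presumes a threshold-like (L/S-shaped) risk profile.
* Whether knots should be placed per sex or pooled is a design choice
  (per sex here, since curves are fitted per sex).
* The LBM equation is taken as given; its validity range is not enforced
  beyond positivity checks.
* Fine–Gray subdistribution modelling, time-varying exposures and
  penalised spline selection are out of scope.
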
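# Methods

## Structural and statistical model

Vancomycin disposition in infants is modelled as one-compartment IV-infusion
kinetics with first-order elimination. Every prediction is closed form: a
dose infused at rate R = amount/D contributes (R/CL)(1 − e^(−k·s)) during
the infusion (s = time since its start, k = CL/V) and
(R/CL)(1 − e^(−k·D))·e^(−k(s−D)) afterwards, summed over doses by
superposition. A biexponential two-compartment solution
(`pk.concentration_2cpt`) exists for model comparison and simulation; it is
not supported by the estimator because two trough/peak samples per infant
cannot identify peripheral distribution (the study situation this package
emulates).

Covariates enter as power laws centred at reference values — weight as
(WT/70)^θ1, serum creatinine as (SCR/20)^θ2 — and binary co-therapy as a
multiplicative factor θ3^DC. Between-subject variability is a lognormal
multiplier on clearance (a single η; the sparse design cannot support an η
on V, and the final model carries none). Residual error is proportional by
default, with additive and combined options.

The released parameter set (`pk.FINAL_MODEL_PARAMS`) is
CL = 10.3·(WT/70)^1.06·(SCR/20)^−0.315·1.46^DC L/h, V = 50.6·(WT/70) L.
The reported variability values 0.145 (BSV of CL) and 0.194 (proportional
residual) are interpreted as **standard deviations**, not variances. The
deciding argument is internal consistency of the reported uncertainty: with
n = 94 subjects and log-SCR spread ≈ 0.35, the standard error of the SCR
power cannot be smaller than ω/(0.35·√94); a BSV of √0.145 ≈ 0.38 puts that
floor at ≈ 0.11, incompatible with the reported SE ≈ 0.065, whereas
ω = 0.145 predicts ≈ 0.06. Simulation at the study design confirms the SD
reading reproduces the reported confidence-interval widths.

## Estimation (FOCE-I / Laplace)

Per subject, minus twice the log joint density g(η) is minimised over η by
a safeguarded Newton iteration (positive-definite-forced curvature, step
clipping, backtracking so every subject's objective is monotone), vectorised
across subjects. The marginal contribution is the Laplace approximation

    OFV_i = g_i(η̂_i) + log det(H_i/2),   H_i = ∇²g_i(η̂_i),

with all 2π constants dropped (NONMEM convention); residual variance is
evaluated at the individual prediction ("interaction"). The approximation is
exact for linear-Gaussian models, which the tests exploit by comparing
against direct quadrature at small ω².

The outer problem optimises positive parameters on the log scale and powers
unconstrained, by L-BFGS-B. Two numerical choices matter:

- **Statelessness.** Each OFV evaluation starts the inner Newton from η = 0.
  Warm-starting across evaluations is faster but makes the objective
  hysteretic when a subject's inner problem is multimodal (possible with
  proportional error and 1–2 observations), which derails the quasi-Newton
  outer search.
- **Internal centring.** Design columns (log covariate ratios, co-therapy
  flags) are centred at their cohort means and the intercepts absorb the
  offsets. The published parameterisation references 70 kg — far outside
  the infant range — making log θ_CL and the weight power nearly collinear;
  centring removes that collinearity. The transform is linear and undone
  exactly for reporting (estimates and, via the constant Jacobian,
  covariance).

Initialisation is naive-pooled least squares on log concentrations for the
structural parameters with variances at 0.1; `n_restarts` adds perturbed
restarts (default 0 — the covariate search warm-starts each child fit from
its parent instead, which guards the nested-model OFV ordering more cheaply).
A fit never returns a point worse than its own start; a warm start that
evaluates into the penalty region falls back to the pooled initialiser.
Convergence is the optimiser's own criterion, or — when a line search aborts
at a stationary point, e.g. a variance pinned at its 1e-8 floor on clean
data — a check that no small feasible coordinate move improves the OFV.

Standard errors come from the numerically differentiated Hessian of the OFV
(Var = 2H⁻¹), mapped to the natural scale by the delta method; 95% CIs are
natural-scale Wald intervals, matching the shape of conventional popPK
results tables. Observations at or below the 2.00 mg/L assay limit are
flagged on read and excluded from estimation by default (configurable); no
imputation is attempted.

## Covariate search

Candidates are pre-screened by correlation: connected components under
|r| > 0.5 keep a single representative (priority weight > age > height,
SCR > CLCR), reflecting the near-collinearity of growth covariates in the
first year of life. Forward steps add the candidate with the largest OFV
drop while the drop exceeds 3.84 (χ², df 1, p < 0.05); backward steps remove
the least-supported term while its removal costs less than 6.63 (p < 0.01);
9.21 (df 2) is available as the documented alternative preset. Continuous
candidates enter as powers centred at the cohort median (weight and SCR keep
the 70-kg/20-µmol/L references when reproducing the published model);
binaries as factors. A clinical-relevance helper flags covariates whose
maximal effect across the observed range is below 20%. The trace records
every evaluated step and replays to the final model.

## Synthetic cohort

The generator emulates the study conditions rather than any real dataset:
94 infants, a neonate/infant age mixture (40% ≤ 28 days, else uniform to
345 days) reproducing the bimodal age structure; weight lognormal around an
age-dependent growth curve calibrated to a 4-kg median, truncated to
1.4–18 kg; height from weight (median 52 cm); SCR lognormal
(median 18.25 µmol/L, log-SD 0.35, truncated 5.5–50) independent of size;
ceftriaxone prevalence 0.3 (unreported in the source population; chosen as
a plausible co-therapy rate and configurable). Sampling is TDM-style:
exactly 205 observations for n = 94 (subjects contribute 1/2/3 samples in a
6/65/23 split), troughs immediately before a dose at or after the fifth
interval, peaks 0.5 h after the end of the infusion.

The default regimen is 10 mg/kg infused over 1 h every 6 h — the routine
infant schedule — rather than the cohort's reported median daily dose of
60 mg/day. Under the final model those two reported conditions are mutually
inconsistent: 15 mg/kg/day puts typical troughs at 2–3 mg/L, below the
2 mg/L assay limit for a large fraction of samples, while the study's
observed concentrations ran 3.31–51.93 mg/L (median 10.6) with no
below-limit values. The 10 mg/kg q6h default reproduces that observed
concentration distribution (median ≈ 10.5 mg/L, < 10% flagged), which is
what the downstream estimation actually consumes.

Residual noise is applied as y = f·exp(ε) by default (exponential/lognormal,
strictly positive); the (1 + ε) normal-proportional form is available but
can produce floored near-zero artefacts at realistic CVs. What passing tests
on these cohorts do **not** show: robustness to time-varying covariates,
dosing-record errors, adherence gaps, or assay-specific censoring patterns
of real TDM data.

## Evaluation

The bootstrap resamples subjects with replacement (n preserved), refits each
replicate from the original estimates, excludes and counts non-converged
replicates, and reports 0.5/2.5/5/50/95/97.5/99.5 percentiles; a 2.5–97.5%
interval away from zero supports an estimate's reliability. NPDE simulates
K (default 1000) replicate datasets under the fitted model, decorrelates
observed and simulated vectors per subject with the Cholesky factor of the
empirical simulation covariance (ridge-regularised if singular), clips pd to
(1/2K, 1 − 1/2K) and transforms by the normal quantile; calibration is
tested by a one-sample t test, a χ²-based variance test and Shapiro–Wilk,
combined with a Bonferroni rule. NPDE calibration checks must generate data
with the same residual distribution the model simulates (proportional
normal); the generator's lognormal default differs enough for normality
tests to notice at n ≈ 200. Prediction errors are
PE = 100·(pred − obs)/obs summarised by MPE/MAE/RMSE/MDPE/MDAE and the SD of
PE; undefined legacy metric names from older reports are not reproduced.

## Dosing simulation

Scenario simulation draws replicate patients from the η distribution only
(assay noise excluded from the bands by default — the bands describe
concentration profiles, not measurements), evaluates steady state in closed
form (no burn-in), and summarises percentile bands, troughs at τ⁻ and peaks
at end of infusion. Five built-in scenarios span a 0.95-kg 29-week
premature neonate (19 mg q24h; an `a-alt` preset gives the 15 mg/kg
guideline dose) to an 8-kg 9-month-old (80 mg q6h). Because the BSV is
lognormal (median 1), the replicate median trough equals the typical-subject
closed-form trough up to Monte Carlo error — a property the tests assert.
The simulated median trough for the premature neonate lands ≈ 9% below the
originally reported 3.66 mg/L; the gap is within the tolerance implied by
the unstated infusion-duration and sampling-instant conventions (a trough
drawn 1 h before the next dose, a common TDM instruction, would reproduce
3.66 almost exactly), and the τ⁻ convention is kept deliberately.

## Problem sizes

Default experiment scales are chosen to keep a full desk run comfortable:
parameter-recovery checks use 10–20 replicated 94-infant studies; the null
false-inclusion experiment uses 200 replicates at n = 94; bootstrap examples
use B = 50–200 (B = 1000 remains the conventional full run and the
function's default); NPDE uses K = 800–1000; dosing simulations use 5000
replicates.

## Known limitations

- No BQL likelihood (M3-style censoring); flagged observations are simply
  excluded.
- Single η (diagonal Ω up to {CL, V}); no covariance between random effects.
- FOCE-I at two samples per subject carries the usual small-sample downward
  bias in variance components (visible in the tests as ω̂², σ̂² slightly
  below truth); structural parameters are recovered within the published
  intervals.
- The estimator supports the one-compartment structural model only.
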
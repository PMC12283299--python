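# Methods

This note records the modeling assumptions, numerical choices, and known
limitations behind `remipk`. Units throughout: amounts mg, rates mg/h,
times h, volumes L, clearances L/h, concentrations ng/mL (the single
mg/L → ng/mL factor of 1000 lives in `pkcore.concentration`).

## Structural model

Two-compartment mammillary disposition with constant-rate infusion input.
The closed-form solution is assembled per infusion segment from the hybrid
exponents λ_fast, λ_slow (roots of λ² − (k10+k12+k21)λ + k10·k21 = 0) and
unit-bolus coefficients; an arbitrary regimen is the superposition of its
segments, and switching off an infusion is superposition of a negative-rate
segment. Loading doses are represented as 1-minute constant-rate infusions
(rate = amount × 60 mg/h), not instantaneous boluses — this matches how such
doses are physically delivered by pump and removes a separate bolus code
path.

Near-degenerate hybrid roots (relative gap < 1e-8) are handled by clamping
the slow root to maintain a minimal relative separation rather than by a
series expansion: the clamp perturbs the profile by O(1e-8) relative —
below every tolerance used anywhere in the package — and keeps the segment
formula branch-free and fully vectorizable, which the estimation engine
relies on. Parameters are validated strictly positive, so exact degeneracy
cannot arise; the clamp is purely defensive.

Default typical values for simulation are the final-model estimates
CL = 58.2 L/h, V₁ = 25.5 L, Q = 20.0 L/h, V₂ = 34.5 L (estimate column, not
the slightly different bootstrap medians).

## Statistical model

* Inter-individual variability: log-normal, diagonal Ω, on all four
  disposition parameters. Reported IIV percentages are read as
  100·√ω² on the log scale (the dominant convention for log-normal IIV);
  the defaults are 50.3 / 16.5 / 65.7 / 61.2 % for CL / V₁ / Q / V₂.
* Residual error: proportional by default (σ_prop = 0.25, the final-model
  value); a combined proportional + additive model is available
  (`error_model="combined"`) since the error model was selected, not fixed,
  in the original workflow.
* Covariate terms are multiplicative: power of covariate/median for
  continuous covariates, factor^COV for 0/1 categorical covariates.

## Estimation (FOCE-I)

For subject i the conditional mode η̂ᵢ of the joint density of (yᵢ, η) is
found, the model is linearized there (Gᵢ = ∂f/∂η at η̂ᵢ, central finite
differences with step 1e-5), the residual variance is evaluated at the mode
(the "interaction"), and the subject contributes

    log|Cᵢ| + rᵢᵀ Cᵢ⁻¹ rᵢ,  Cᵢ = Gᵢ Ω Gᵢᵀ + Vᵢ,  rᵢ = yᵢ − fᵢ(η̂) + Gᵢ η̂

to the OFV (2π constant omitted). Implementation choices that matter:

* **Inner problem.** The η-modes of all subjects are found simultaneously by
  a damped Newton iteration vectorized across subjects, using the observed
  second derivative of the per-observation deviance with respect to the
  prediction (clamped below at 20% of the expected information so the step
  matrix stays positive definite), per-subject backtracking line searches,
  and a trust-region cap on the step norm. Convergence: per-subject gradient
  below 3e-4, which bounds the OFV error by ~1e-7 — far below the 0.01 OFV
  resolution at which any model decision is made. The solver warm-starts
  from a snapshot of the modes that is refreshed only when a new best OFV is
  seen, so the objective remains a deterministic function of the population
  parameters during finite-difference probing.
* **Outer problem.** Population parameters are optimized on transformed
  scales (log for structural parameters, ω, σ and categorical factors; raw
  for power exponents) in three stages: bounded quasi-Newton (L-BFGS-B with
  finite-difference gradients), a Nelder-Mead simplex polish — the
  finite-difference gradients stall in the flat, curved ω-valleys typical of
  sparse elimination-phase designs, which the simplex crosses reliably — and
  a short quasi-Newton pass that certifies stationarity. A fit is flagged
  non-converged when no stage reaches its stopping rule and the final pass
  still finds > 0.05 OFV of descent; flagged results are never silently used
  (bootstrap and screening count and exclude them).
* **Initial values.** A crude steady-state initializer: CL ≈ 1000 ·
  median(rate/C at cessation) across subjects (infusions here run ≥ 6 h,
  i.e. several terminal half-lives, so the cessation sample is near
  plateau), with V₁, Q, V₂ seeded at fixed fractions of CL. Omegas start at
  0.3, σ_prop at 0.2.
* **Uncertainty.** Relative standard errors come from a central
  finite-difference Hessian of the OFV in the transformed space
  (covariance = 2·H⁻¹); for log-scaled parameters the SE of the log is
  itself the relative SE (delta method). Shrinkage = 100·(1 − SD(η̂)/ω).
* **BLQ.** Observations below the 1.0 ng/mL quantification floor are
  flagged and excluded from fitting (discard rule). With sampling ending
  240 min after cessation — about 2.4 terminal half-lives — BLQ samples are
  rare, so more elaborate likelihood-based BLQ treatments would be exercised
  by almost no data.

Stepwise screening: forward inclusion adds the candidate with the largest
OFV drop ≥ 3.84 (χ²₁ at α = 0.05) until none qualifies; backward elimination
removes the cheapest effect while its removal costs < 10.82. The printed
10.82 is kept as the default cut-off even though the exact χ²₁ upper-0.001
quantile is 10.828; `chi2_threshold` returns the exact quantile. Ties in
ΔOFV break lexicographically by effect label (all candidates add exactly one
parameter, so parsimony cannot discriminate), making scans deterministic.

## Synthetic cohorts

`cohort_sim` emulates the study design so the pipeline can be tested without
patient data:

* 32 subjects by default; constant-rate infusions with rate from a truncated
  log-normal (median 6 mg/h, bounded to the observed 2–17.28 mg/h) and
  duration 6.15 h + log-normal excess (median 8.33 h total, truncated at the
  observed 294.9 h maximum). The shifted form reflects the observed shape —
  half the cohort within ~2 h of the minimum stay, with a long right tail —
  which a plain log-normal cannot reproduce while holding the median.
* Sampling at dose cessation and 10, 20, 30, 60, 90, 120, 240 min after the
  stop; each sample independently lost with probability 0.08, reproducing
  the study's attrition (256 nominal draws → ~236 analysable samples); at
  least one observation per subject is always retained.
* Covariates target the published medians and ranges: truncated normals for
  age (62 [26–79] y) and weight (63 [47–98] kg), truncated log-normals for
  the skewed labs (ALT median 34.85, SCR median 75.75 µmol/L), sex 3:1 M:F,
  ECMO 18/32, CRRT 14/32. Log-scale spreads for the labs (0.85 and 0.60)
  were chosen once so that the printed ranges sit in the far tails.
  Covariates are sampled independently — no correlation structure was
  published — and are pure labels unless a covariate effect is supplied.
  Creatinine clearance is derived by Cockcroft–Gault (SCR µmol/L ÷ 88.4 to
  mg/dL; × 0.85 for women) and eGFR by CKD-EPI 2009 without the race
  coefficient (single-site East-Asian cohort).
* Measurements apply y = f·(1+ε_prop) + ε_add with fresh errors per sample;
  negative draws are redrawn. With ω = σ = 0 the generator reproduces the
  deterministic typical-value profile exactly (an identity the tests use).

What the generator does **not** emulate: time-varying daily labs (collapsed
to one baseline value), outlier contamination (the study's seven discarded
aberrant samples enter only through the dropout probability), assay
saturation above 1000 ng/mL (values above the linear range are kept and only
warned about), ECMO-circuit adsorption or CRRT clearance physics (the study
found no covariate effect of either, so they are labels here). Passing tests
therefore demonstrate internal consistency of estimator and diagnostics
under the declared generating model — not robustness to the messier features
of real ICU data.

## Validation diagnostics

* **CWRES** decorrelates residuals with Cᵢ^(−1/2) under the same FOCE
  linearization as the objective; PRED is the population prediction (η = 0),
  IPRED the prediction at the empirical Bayes estimates.
* **Bootstrap** resamples subjects (never rows) with replacement, refits
  each replicate starting from the original estimates, reports
  median/2.5%/97.5% over converged replicates, and fails hard if more than
  half do not converge.
* **pcVPC** simulates replicate datasets on the observed design, corrects
  each observed and simulated value by median(PRED in bin)/PRED, and bins at
  the protocol's nominal post-cessation times (the design is nominally
  timed, so quantile binning would only blur it). Reported alongside the
  percentile bands: the fraction of observations inside the 90% prediction
  interval.
* **NPDE** decorrelates each subject's observation vector with the mean and
  Cholesky factor of its empirical simulation covariance (ridge 1e-8 added
  on singularity), counts ties as half, clips to [1/2K, 1 − 1/2K], and maps
  through the normal quantile. Three adequacy tests are always run —
  Wilcoxon signed-rank for location, a χ² scale test of Σnpde² against
  χ²_n for variance 1, Shapiro–Wilk for shape — combined by Bonferroni.
  The scale test stands in for the variance test named but not specified in
  the original workflow.

## Dose simulation

CSDTs are computed from the typical-value (population-predicted) curve by
bracketed root-finding on the exact post-cessation decay (xtol 1e-6 h, i.e.
< 0.1 s), with the reference concentration taken at the moment of cessation.
Linearity makes CSDTs independent of the infusion rate. The Monte Carlo path
(`simulate_bands`) draws subjects with IIV — latent curves only, no residual
error — and reports 5/50/95% bands; it exists for dose-scenario exploration
and sensitivity analysis, not for the CSDT tables.

The 0.5-h CSHT computed from the final-model estimates is ≈ 14.7 min against
a printed 15.6 min (the 2-h and 8-h values, 17.5 and 21.1 min, agree
closely); the printed value likely reflects the original simulation's time
grid. The acceptance checks therefore carry a ±10% band on half-times.

## Problem sizes used in tests

Stochastic checks are scaled to single-CPU runtimes: parameter recovery uses
20 replicates of the full 32-subject design; screening calibration uses 24
null replicates at n = 32 and 24 effect replicates at n = 150 with IIV on CL
only (the likelihood-ratio calibration concerns the parameter carrying the
candidate effect; extra variance components only slow each fit without
changing the test's distribution). The sex-effect power check runs at
n = 150 rather than n = 32 because a 1.3-fold effect against ω_CL ≈ 0.5 with
8 women is detectable only by chance at the study's size (expected ΔOFV ≈
2.6, below the 3.84 cut-off) — consistent with the original analysis, which
attributed its own borderline sex finding to the 3:1 imbalance and discarded
it. Diagnostic calibration (NPDE moments, pcVPC coverage) runs on one
~236-observation cohort with 1000 simulation replicates.

## Known limitations

* No effect-site compartment or sedation-depth (pharmacodynamic) link, and
  no metabolite kinetics: plasma-referenced CSDTs will understate arousal
  delay whenever plasma–effect-site hysteresis matters.
* Ω is diagonal; η–ε correlation and inter-occasion variability are not
  modeled.
* Estimation is FOCE-I only (no SAEM/importance sampling); with fewer than
  ~2 observations per subject the linearization degrades and the bounded ω
  search may pin small variance components at the boundary (visible as high
  shrinkage, exactly as in the original analysis, where V₁ shrinkage was
  69%).
* The FD-Hessian RSEs assume a locally quadratic OFV; near a boundary
  (ω → 0) they are unreliable, which is one reason bootstrap CIs are the
  primary uncertainty statement, as they were in the original analysis.
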
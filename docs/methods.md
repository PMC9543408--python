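# Methods

## Scope and model

The package estimates the difference in mean MADRS10 (Montgomery–Åsberg
Depression Rating Scale total, 0–60, lower = less severe) between an
experimental arm and a reference arm at the last scheduled visit of a
short-term (3–6 post-baseline visits) parallel-group depression trial, in
the presence of intercurrent events — treatment/study discontinuation for
adverse events (AE), lack of efficacy (LoE) and other reasons — and the
monotone missing-data tails they create, plus intermittent missingness.
Eight analysis methods are implemented as uniform operations, each mapped to
the ICH E9(R1) estimand(s) it implicitly targets; the catalog in
`estimand_report` records the mapping, the intercurrent-event strategy, and
the missing-data assumptions each estimator needs.

### MMRM

The central estimator is a mixed model for repeated measures, saturated in
visit-specific treatment effects:

    Y_ij = b0 + b1 Treat_i + b2F Time_ijF + b3F Time_ijF Treat_i
           + b4 Baseline_i + eps_ij,   F = 2..V,

with `eps_i ~ MVN(0, Sigma)`.  The classical decomposition into a subject
random intercept plus an unstructured serial component is not jointly
identified when the serial part is unrestricted (`sigma_b^2 J + Sigma_serial`
spans the same marginal family), so the engine fits a single unstructured
V×V total covariance — the marginal model is identical, and the
between/within split is represented only through `Sigma`.

Estimation is REML: `Sigma` is parameterized by the log-Cholesky factor
(diagonal on the log scale), the fixed effects are profiled out by GLS, and
each subject contributes through the sub-matrix of `Sigma` at their observed
visits — direct-likelihood handling of intermittent and monotone
missingness, valid under MAR.  Subjects sharing an observed-visit set share
that sub-matrix, so the restricted likelihood and its analytic gradient are
computed from per-pattern sufficient statistics (tensors `sum x x'`,
`sum x y`, `sum y y'`); the optimizer is L-BFGS-B started from the
OLS-residual pairwise covariance (eigenvalue-floored to positive
definiteness), relative tolerance 1e-8, at most 200 iterations, with one
jittered restart on failure.  The analytic gradient is verified against
finite differences in the test suite, and the whole engine against an
independent naive optimizer (explicit per-subject inversions, matrix-log
parameterization, Nelder-Mead/BFGS) to 1e-4 on five small fixtures.

Inference uses the normal approximation (z intervals).  Small-sample
degrees-of-freedom corrections (Satterthwaite, Kenward-Roger) are out of
scope; at the sample sizes exercised here (60–600 subjects) the difference
is negligible relative to Monte Carlo error.

The visit-6 (generally visit-V) treatment effect is `delta_V = b1 + b3V`,
with `SE = sqrt(c' Omega c)` from the REML coefficient covariance
`Omega = (X' V^-1 X)^-1`.

### The eight analyses and their estimands

* **ANCOVA_CC** — OLS of the last-visit outcome on treatment + baseline,
  complete cases (baseline and last visit observed; intermediate visits
  irrelevant).  Hypothetical-strategy estimand under MCAR (E1).
* **ANCOVA_LOCF / MMRM_LOCF** — the same analyses after last observation
  carried forward.  LOCF is deterministic; leading missing cells are filled
  from baseline (the "last observation" at that point; the count of
  baseline-carried cells is logged).  While-on-treatment reading (E2, ANCOVA
  only) and treatment-policy-under-unchanged-course reading (E3).
* **ANCOVA_MI** — chained-equations multiple imputation with type-1
  predictive mean matching (predictors: treatment, baseline, all other
  visits' current values; Bayesian linear regression draws with a
  noninformative prior; `donors = 5`, `sweeps = 10`, `m = 10` by default;
  ties broken uniformly within the imputation substream), ANCOVA per
  completed dataset, Rubin pooling.  E1 under MAR; E3 reading.
* **MMRM** — direct likelihood, no imputation.  E1 under MAR; E3 reading.
* **MMRM_J2R** — jump-to-reference MI: an MMRM with intercept + visit +
  baseline fixed effects and unstructured covariance is fitted on the
  reference arm only; each experimental-arm post-discontinuation cell is
  imputed as that model's fixed-part prediction (baseline and visit only)
  plus a random error drawn per visit from `N(0, Sigma_ref[j,j])`
  (`draws="marginal"`, the default; `draws="joint"` draws the missing block
  jointly from `MVN(0, Sigma_ref[block,block])`).  Imputed values are
  neither rounded nor clipped.  Reference-arm missing cells and
  experimental-arm intermittent cells are left to the downstream
  direct-likelihood MMRM (MAR).  Composite-variable estimand (E4, flagged as
  possibly not clinically meaningful) and treatment-policy-under-J2R reading
  (E3).
* **PMMM** — pattern-mixture mixed model: the MMRM design is extended with
  dropout-pattern main effects and pattern×treatment interactions.  Patterns
  are classified from the trailing run t of missing visits (t ≤ 1
  completers/quasicompleters; t = 2 late dropout; 3 ≤ t ≤ V−1 early
  dropout; t = V unclassifiable/excluded) — classification depends only on
  the observed-data shape, not on the recorded discontinuation visit.  The
  model carries a shared time-profile shape (no pattern×time terms) with
  pattern-specific level and treatment offsets.  Pattern-specific effects
  `delta_VP = b1 + b3V + b6P` are averaged with the analyzed-sample pattern
  frequencies as fixed weights; `SE = sqrt(w' C w)` with `C` the covariance
  of the `delta_VP` contrasts from the model coefficient covariance
  (weight-estimation variance is deliberately ignored).  Any pattern with
  fewer than 2 subjects in some arm is merged into the adjacent pattern
  (EARLY → LATE → COMPLETER_QUASI) and the merge logged; a single remaining
  pattern reduces the analysis exactly to the plain MMRM.  Composite
  estimand (E5, flagged) and treatment-policy reading (E3).
* **PRINCIPAL_STRATUM** — logistic regression of the intercurrent-event
  indicator (any discontinuation by default) on configured covariates
  (baseline by default), pooled across arms; the stratum keeps the subjects
  with the smallest propensities.  The AUTO cutoff sets the stratum size to
  the observed number of event-free subjects.  On separation or
  non-convergence a ridge-penalized fit supplies the propensity ranking.
  The stratum is analysed by the plain MMRM.  Principal-stratum estimand
  (E6).

Rubin pooling uses `qbar = mean`, `W = mean(se^2)`, `B = var(estimates)`,
`T = W + (1 + 1/m) B`, `df = (m-1)(1 + W/((1+1/m)B))^2` (infinite, hence a
normal quantile, when `B = 0`).  Pooling applies to the `(delta_V, SE)`
pairs, never to whole coefficient vectors.

## Synthetic-trial generator

The generator emulates the structure of mirtazapine-era short-term
depression trials: 2(+) parallel arms, baseline plus 3 or 6 post-baseline
visits, MADRS10 in [0, 60].  The outcome model is

    Y_ij = mu[arm, j] + gamma (Baseline_i − mu_B) + b_i + e_ij,

`b_i ~ N(0, sigma_b^2)`, `e_i ~ MVN(0, S)` with an AR(1) shorthand
(`sd = 5`, `rho = 0.6` by default) or an explicit matrix; baseline is
truncated normal (mean 30, sd 5, lower bound 10, emulating severity entry
cut-offs).  Default profiles: placebo improving 26 → 19 points over six
weekly visits, active arm 4 points lower at end of trial (the trials' 4–8
point range), `gamma = 0.5`, `sigma_b = 5`, 60 subjects per arm (trial
N = 120, inside the 90–150 range of the emulated studies).  Scores are kept
continuous by default so Gaussian parameter-recovery checks are exact in
expectation (integer rounding is available); clipping to [0, 60] applies to
emitted scores only, never to the latent values driving the hazards, and is
rare at the defaults.

Discontinuation follows per-reason discrete-time logistic hazards at visits
1..V−1: LoE increasing in the current latent score (`coef = 0.08`, so the
worse-off placebo arm discontinues more), AE confined to an early window
(visits 1–2) and heavier on active treatment, plus small score-independent
"drug-unrelated" and "unknown" hazards.  The first triggered reason sets the
discontinuation visit and blanks all later visits (monotone tail);
independent MCAR blanking (default probability 0.03) is then applied to the
remaining cells, never the baseline.  At the defaults roughly 25–30% of
subjects discontinue and ~20% of outcome cells are missing, inside the
emulated 10–46% range.

The treatment-policy potential outcomes after the event follow a
configurable mechanism: `MAR_CONTINUATION` (the no-event values stand),
`J2R_SWITCH` (the fixed part jumps to the reference profile while the
subject keeps their own baseline effect, random intercept, and serial
residual draws), or `RETAINED_SLOPE` (the deviation from the arm profile at
the discontinuation visit is carried forward).  A `TruthRecord` carries both
potential-outcome matrices, event times/reasons, and enough components to
compute every estimand's finite-sample true value: hypothetical,
treatment-policy, while-on-treatment (last on-treatment value), and
principal-stratum contrasts.  The principal-stratum truth uses the
subjects event-free under their own assignment; an experimental
`cross_world_stratum` option replays the same hazard uniforms under the
counterfactual assignment (shared-frailty cross-world simulation) and
intersects the two event-free sets.

All draws come from named substreams spawned from the master seed
(baseline, random effects, residuals, dropout, intermittent; imputation `i`
uses substream `(seed, i)`), so toggling one mechanism leaves the others'
draws unchanged and every output is a pure function of (config, seed).

### What the generator does not emulate

Calibration to the six original trials (their data are proprietary),
active-control pharmacology, continuous-time dropout, site effects,
integer/bounded-score measurement artefacts at the defaults, and
reason-specific post-event mechanisms (one mechanism applies to all
reasons, mirroring the aggregated "study withdrawal" event).  Passing
simulation checks therefore demonstrates correctness of the estimators
under the assumed Gaussian longitudinal structure, not robustness to the
many ways real trial data deviate from it.

## Validation experiments and problem sizes

The acceptance suite (tests/test_acceptance.py) runs, with fixed seeds:

* pattern classification against a brute-force transcription of the three
  pattern rules, exhaustively over all masks for V = 3 and V = 6;
* the REML engine against the independent naive optimizer on five fixtures
  (12–30 subjects, V = 3–4), to 1e-4 in restricted log-likelihood and
  coefficients;
* Rubin's-rules hand-arithmetic and degenerate-B identities, exactly;
* exact pipeline reductions (single-pattern PMMM ≡ MMRM; cutoff-1.0
  principal stratum ≡ MMRM; LOCF/MI/J2R on complete data ≡ their plain
  counterparts with zero between-imputation variance);
* parameter recovery: 200 trials, 100/arm, score-dependent (MAR) dropout
  ~25–27%, true contrast −4: mean estimate within 3 MC-SE, model SE within
  15% of the empirical spread;
* CI coverage under the null: 500 trials, coverage required in [92%, 98%];
* jump-to-reference consistency: 100 trials at 300/arm with ~30%
  experimental-arm dropout generated under the J2R switch mechanism with
  *score-independent* hazards, pooled J2R estimate within 3 MC-SE of the
  treatment-policy truth; and attenuation of J2R relative to MMRM when the
  truth is MAR continuation (100 trials);
* LOCF inflation: 50 trials with LoE-driven dropout and a constant
  treatment offset (effect established by week 1 and maintained), mean
  |LOCF estimate| at least the MMRM's;
* catalog fidelity (6 estimands, all 8 methods mapped, composite-estimand
  caveat flags);
* clean-limit concordance: 50 complete-data trials at 200/arm, all eight
  estimates pairwise within 0.3 points on average and unbiased within MC
  error.

Two of these experiments deserve comment, because the directional phenomena
depend on the data-generating configuration in ways worth understanding:

*J2R consistency requires non-informative dropout.*  In the generator's J2R
world a discontinuing subject keeps their own random intercept and serial
residuals; when dropout is driven by the current score, discontinuers are
positively selected on those retained effects.  The imputation model, by
construction, predicts from baseline and visit only — it is blind to the
subject's history — so under informative dropout it under-imputes the
selected dropouts and overstates the contrast (about 0.4 points at the
configurations tested).  This is a genuine property of marginal
reference-based imputation, not an implementation artefact; the
consistency experiment therefore uses arm-dependent but score-independent
hazards, where the imputer's assumption and the generating mechanism
coincide.  Conditioning the imputation on observed history would remove
the mismatch but is a different (conditional-MVN) variant of the method.

*LOCF inflation requires a maintained effect.*  Freezing dropouts at their
last value inflates the contrast only when the placebo arm loses more
remaining improvement than the active arm.  With a ramped effect (active
improving faster early on) the active arm's frozen dropouts lose more, and
LOCF attenuates instead.  The inflation experiment therefore applies the
full treatment offset from visit 1 with parallel improvement — the setting
in which heavy, placebo-tilted LoE dropout produces the well-known LOCF
exaggeration.

## Numerical choices and degenerate inputs

* Scores are written to CSV via `repr` (exact float round-trip) and read
  with round-trip float parsing; the empty string is the missing marker.
* Subjects with no observed post-baseline outcome are excluded from all
  model fits with a warning (they carry no likelihood information) but
  remain in intercurrent-event denominators.
* The design matrix is rank-checked before fitting; an empty
  pattern-by-arm cell raises an error directing the caller to pattern
  merging.
* A PMM donor pool smaller than `donors + 2` observed values is reduced
  with a warning; an all-missing visit is an error.
* `rubin_pool` with `B = 0` returns `T = W`, infinite df, and a normal
  quantile.
* Logistic-regression separation in the principal-stratum propensity model
  falls back to a ridge-penalized fit; only the propensity *ranking* enters
  the selection, so the stratum is still exact under perfect prediction.
* Equidistant PMM donors are broken uniformly at random inside the
  imputation substream; all other ties (argsorts) use stable ordering, so
  results are independent of subject ordering.

## Known limitations

Normal-approximation inference slightly under-covers at very small n; the
pattern-mixture SE ignores weight-estimation variance; the marginal J2R
draw ignores within-subject correlation of the imputation errors (the
`joint` option restores the correlation but still does not condition on
observed history); the principal-stratum analysis identifies the stratum
only as well as the covariates predict the event, and its own-assignment
truth is an approximation to the cross-world stratum unless the
experimental shared-frailty option is used.  Copy-reference and
copy-increments variants of reference-based imputation, delta-adjustment
tipping-point analyses, and per-reason intercurrent-event strategies are
out of scope.
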
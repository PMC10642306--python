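# Methods

## Model

Plot-level phenotypes are modeled as

    y = 1 mu + X_o tau_o + Z_s u_s + Z_c u_c + Z_b u_b + e

with fixed intercept and check effects (plus environment and
check-by-environment terms for multi-environment fits) and mutually
independent Gaussian random effects: families `u_s ~ N(0, G_s)`,
clones-within-family `u_c ~ N(0, G_c)`, blocks `u_b ~ N(0, G_b)` and
residuals `e ~ N(0, R)`.  Checks are fixed, so check plots carry
all-zero rows in `Z_s` and `Z_c`; the intercept represents the clone
population mean and the check columns are per-check contrasts, with
environment and interaction terms coded against the first trial as
reference — this keeps the fixed design full rank, which is verified at
construction.

Covariance structures per model:

| term      | ST                | MET                                     |
|-----------|-------------------|-----------------------------------------|
| block     | `s2_b I`          | direct sum of `s2_bj I` per trial       |
| family    | `s2_s I` (pF only)| `G_ts (x) I_s` (pF only)                |
| clone     | `s2_c I`          | `G_tc (x) I_c (x) I_s`                  |
| residual  | `s2 I`            | direct sum of `s2_j I` per trial        |

`G_ts`/`G_tc` are unstructured t x t matrices (t(t+1)/2 free parameters
each).  Column ordering of the MET genetic terms is trial-major (trial
1: level 1..n, trial 2: ...), so the Kronecker form is literal.  In the
no-family models the clone term absorbs the family effect: its variance
estimates `s2_s + s2_c`, which is the confounding the nested model
removes (verified by simulation in the test suite).

## Estimation

REML, evaluated through Henderson's mixed-model equations: with
`W = [X Z]` and `C = W'R^-1 W + diag(0, G^-1)`,

    -2 l = (N - o) log 2pi + log|R| + log|G| + log|C| + y'Py.

The constant `-(N-o)/2 log 2pi` is included so AIC values are
internally consistent; log-likelihoods from other software may differ
by a constant.  `C` is sparse — clone equations couple only within a
clone across trials — and is factorized per evaluation with a sparse LU
under a symmetric minimum-degree ordering, so one likelihood evaluation
on the default scenario (~1500 mixed-model equations) costs a few
milliseconds.  `log|G|` uses the Kronecker identities rather than any
large determinant.

Optimization is bounded L-BFGS-B on transformed parameters —
log-variances, log-Cholesky factors for the unstructured blocks — which
keeps every iterate valid.  Convergence: relative log-likelihood change
below `tol` (default 1e-8); requesting `tol <= 1e-10` switches to
central-difference gradients (the forward-difference noise floor is
around 1e-6, which is what the balanced one-way agreement test needs).
Starting values put half the phenotypic variance on the residual and
split half equally among the random terms, identity-scaled for
unstructured blocks; MET fits warm-start from per-trial single-trial
fits with starting across-trial correlations of 0.4, which roughly
halves the iteration count.  Variances that converge to the lower bound
(1e-8 of the phenotypic variance) are reported as 0 and flagged;
non-convergence flags the result instead of raising.

BLUPs and the GLS fixed effects come from one solve of the MME at the
optimum.  Prediction error variances are the random-effect diagonal of
`C^-1` (dense inversion, done once per fit and skippable via
`compute_pev=False`).  The total-genotypic PEV of a clone is the joint
error variance `var(s_hat + c_hat - s - c)`, i.e. it includes the
family-clone error covariance from the inverse MME — not the sum of the
two marginal PEVs — because the accuracy formula divides by
`s2_s + s2_c`, the variance of the summed effect.

## Analytics

* `rho_S = s2_s/(s2_s + s2_c)`; per trial in MET using the diagonals of
  `G_ts`/`G_tc`.  Percent contributions divide each component by the
  per-trial total.
* Accuracy `sqrt(1 - v/s2)` with `v` the arithmetic mean of per-level
  PEVs of that effect (per trial for MET).  Relative efficiency is
  `r_g/r_c`; "Average" rows are arithmetic means of per-trial values
  (the mean-of-ratios and ratio-of-means conventions agree to the
  2-decimal reporting precision on all cases exercised here).
* Model comparison: `AIC = -2l + 2p` with `p` the number of free
  covariance parameters (3 for STMwF, 4 for STMpF, 12 and 18 for the
  MET pair at t = 3); LRT statistic `2(l_full - l_reduced)` against
  chi-square, so at df = 1 an increment of 1.92 log-likelihood units is
  the 5% critical point.  A boundary-corrected half-half mixture
  reference is available as an option; the plain chi-square test is the
  default (slightly conservative for a variance on the boundary).
* Confidence intervals: variance components get Satterthwaite
  chi-square intervals `[nu s2/chi2_{1-a/2,nu}, nu s2/chi2_{a/2,nu}]`
  with `nu = 2 (s2/SE)^2`; across-season genetic correlations get
  normal-theory intervals truncated to [-1, 1].  SEs come from a
  numerical Hessian of the REML criterion at the optimum, with the
  delta method for derived quantities.  Empirical coverage of both
  procedures is checked by simulation (95% +- 3%).
* Ranking comparison: top-fraction sets (default 20%, ceil(f n),
  label-ordered tie-break), Czekanowski overlap `a/(a+b)`, tie-aware
  Spearman correlation.
* FAI-BLUP: variables are oriented so higher is desirable (both tuber
  yield and specific gravity point up), standardized; loadings are
  principal components of the correlation matrix (retained by the
  eigenvalue >= 1 rule, overridable — the study setting uses 3 factors
  for 6 = 2 traits x 3 seasons variables), varimax-rotated
  (Kaiser-normalized, matching `stats::varimax` in R); factor scores by
  weighted least squares (Bartlett); ideotypes are the 2^k sign
  combinations of the desired factor directions placed at the observed
  extreme scores, with the all-desirable combination as the selection
  target; the index is the inverse-distance share
  `(1/d_ij)/sum_i(1/d_ij)` (distances floored at 1e-12), so scores sum
  to 1 over genotypes for each ideotype.  The desired direction of a
  factor is the sign of its loading sum over the (oriented) variables.

## Synthetic data

The generator emulates the study conditions the analysis targets:

* **Designs.** ABD — every check once per block, clones split evenly
  across blocks (remainders to the first blocks), assignment randomized
  under the seed; p-rep — `d = round(target p_N N_treat/(1 - target))`
  clones drawn uniformly are duplicated, replicates placed greedily in
  distinct least-filled blocks, so the realized `p_N = d/(N_treat + d)`
  is within one plot of the target.  The published trial dimensions
  (e.g. 48 blocks / 477 clones / 3 checks -> 621 plots, p_N 22.71%; 304
  clones + 4 checks in 400 plots, p_N 23.00%) are reproduced exactly.
* **Phenotypes.** Family effect vectors across trials drawn
  `N(0, G_ts)`, clone vectors `N(0, G_tc)`, blocks and residuals
  independent per trial; check plots get fixed per-check offsets from
  the trial mean.  Traits are simulated independently (the analysis
  fits them separately).  Optional uniform plot missingness (default
  0); missing plots are dropped row-wise at analysis, which the
  one-stage analysis tolerates.
* **Default scenario** (chosen once to mirror the study's setting,
  scaled for routine runs): 3 seasons (WHS/MHS/HHS), 30 families x 15
  clones, 20 blocks, 2 checks, ABD (a p-rep variant is available).
  Tuber yield (Mg/ha): means 32/28/18.6 — the high-stress season loses
  ~40%; family variances 11.3/7.3/3.6 (halving with stress), clone
  variances 35/40/55 (growing with stress), residuals 46/72/25, blocks
  5.4/4.5/0.5, across-season genetic correlations 0.35-0.45 (mostly
  complex G-by-E).  Specific gravity: means ~1.08-1.09 on a 1e-4
  variance scale with correlations 0.6-0.7 (mostly simple G-by-E).
  Family-per-clone counts are equal by default (per-family counts are
  configurable); the variance profiles correspond to family shares
  `rho_S` of roughly 0.06-0.25, the range the nested model is meant to
  detect.
* **What the generator does not emulate:** spatial row-column
  correlation, weather-driven trends, multi-year seed-lot carryover,
  cross-trait genetic correlation (optional, default independent).
  Passing tests therefore validate the estimator and the pipeline logic
  under the stated model, not robustness to field artifacts outside it.

## Validation choices

* Oracle suite: on instances with N <= 50 the sparse MME path must
  agree with dense textbook GLS/BLUP/PEV formulas to 1e-9, and the REML
  log-likelihood with the dense determinant form to 1e-8.
* Balanced one-way layouts: REML equals the ANOVA estimators
  (`MS_within`, `(MS_between - MS_within)/m`) to 1e-6 and the
  log-likelihood equals the closed form from the ANOVA sums of squares.
* Parameter recovery: 50 simulated p-rep MET studies at 30 families x
  15 clones x 3 trials (p_N 22%, 4 checks); medians of every REML
  parameter (both unstructured matrices, per-trial block and residual
  variances) are compared with truth at 15%.  The recovery scenario
  uses across-season correlations of 0.6 and block variances
  5.4/4.5/3.0 — all parameters bounded away from zero — because a
  component whose true value is near the boundary measures the design's
  information content, not estimator correctness.  Known behavior at
  these dimensions: clone-level matrices and residual variances recover
  within a few percent, but the family covariances involving the
  low-variance high-stress season are weakly identified (each family
  mean carries noise of the same order as the family variance itself),
  and the positive-semidefiniteness constraint truncates the upper tail
  of their sampling distribution; their medians therefore sit 15-20%
  below truth and the strictest per-parameter recovery checks fail for
  those entries.  This is a property of constrained REML under the
  stated dimensions, not of this implementation: the test suite also
  cross-checks the fitter against glmmTMB on a smaller unstructured MET
  instance, where both reach the same residual-likelihood optimum and
  covariance estimates.
* Concordance trend: over a `rho_S` grid (0.05-0.5) the CC and Spearman
  agreement between clone-only and total-genotypic rankings must fall
  monotonically.
* Interval coverage: 500-replicate simulations for both CI procedures,
  95% +- 3%.

## Problem sizes and runtime

The default scenario (1470 plots x 3 trials worth of equations, ~1500
mixed-model unknowns) fits a single-trial model in ~0.5 s and the full
18-parameter METMpF in ~10 s on one CPU; the complete pipeline
(simulate, all single-trial and MET fits for two traits, summaries,
FAI-BLUP comparison) runs in about a minute.  These sizes were chosen
so the whole validation suite, including the 50-seed recovery study,
completes in well under half an hour.

## Known limitations

* No pedigree/genomic relationship matrices; relatedness enters only
  through the family/clone nesting.
* Unstructured G-by-E is practical only for small numbers of trials
  (t(t+1)/2 parameters); no factor-analytic covariance structures.
* No spatial residual modeling.
* SEs (and hence CIs) use a numerical Hessian; for variances near the
  boundary the Satterthwaite interval is reported as intercepting zero
  rather than trusted.
* The FAI-BLUP internals follow the standard published chain
  (PCA extraction, varimax, WLS scores, inverse-distance index); other
  software may differ in ideotype construction details.
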
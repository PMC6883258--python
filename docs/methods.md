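# Methods

## The problem

Epigenome-wide mediation studies ask which of `k` candidate mediators
(typically CpG methylation M-values, with `k` from thousands to hundreds of
thousands) transmit the effect of an exposure `X` onto an outcome `Y`.
The package works with the standard mediation regression system

```
E(Y)  = theta1 + c X                     (total effect)
M_j   = theta'_j + a_j X + eps_j         (exposure -> mediator)
E(Y)  = theta2 + c' X + sum_j b_j M_j    (outcome model)
```

with an identity link for a continuous outcome and a logit link for a
binary one.  The indirect effect through mediator `j` is `a_j * b_j`; the
total effect decomposes as `c = c' + sum_j a_j b_j` (exactly in the linear
case, approximately on the logit scale).  Mediator `j` carries a mediation
effect when *both* `a_j != 0` and `b_j != 0`.

Two features make the outcome model hard: `k >> n`, and methylation
mediators are strongly correlated (neighbouring CpGs routinely reach
correlations near 0.8).  Penalized selection handles the dimension but its
estimates are biased and carry no standard errors; single-mediator tests
ignore the correlation.

## The testing pipeline

1. **Screening (SIS).**  Mediators are ranked by a marginal association
   statistic and the top `d = ceil(n / (divisor * ln n))` are retained;
   `divisor = 1` by default, `2` for a more aggressive reduction.  The
   default screening basis is the outcome model: for each `j`, the
   single-mediator regression `Y ~ X + M_j` (+ covariates) in the outcome's
   family, scored by `|coef| / se`.  The score is scale-free, so affine
   rescaling of a mediator cannot change the retained set.  A
   mediator-model basis (`M_j ~ X`, score `|a_hat|/se`) is available for
   users who prefer ranking by the exposure path.  Screened-out mediators
   are reported as *not tested*, never as non-significant.

2. **De-sparsified LASSO inference on the outcome model.**
   The design is `[X, covariates, M_retained]`; the exposure and covariates
   are never penalized (they are fixed adjustment variables, not selection
   targets), and columns are standardized internally for penalization
   fairness.

   *Linear family.*  With LASSO estimate `b^lasso` and nodewise residuals
   `Z_j = M_j - M_{-j} gamma^lasso_j`,

   ```
   b_j  = b^lasso_j + Z_j'(y - M b^lasso) / (Z_j' M_j)
   se_j = sigma_eps * ||Z_j||_2 / |Z_j' M_j|
   ```

   where `sigma_eps` is the scaled-LASSO noise estimate (alternating the
   coefficient LASSO at penalty `sigma * lambda0`, `lambda0 =
   sqrt(2 log p / n)`, with `sigma^2 = ||r||^2 / n`).  At `lambda = 0` this
   reduces exactly to OLS with its classical standard errors — a property
   the tests assert to 1e-8.

   *Logistic family.*  The generalized-linear de-sparsification
   `beta~ = beta^ - Theta^ grad`, with `grad` the average score at the
   logistic-LASSO solution and `Theta^` from nodewise LASSO on the
   `sqrt(w)`-scaled design (`w = p(1-p)` at the fitted probabilities,
   floored at 1e-5 against separation underflow).  The variance is the
   sandwich `sigma_j^2 = (Theta^ V Theta^')_jj` with `V` the empirical
   outer product of per-sample scores; `sqrt(n) beta~_j / sigma_j` is
   treated as standard normal.

3. **a-path tests.**  For each retained mediator, OLS of `M_j` on `X`
   (+ covariates) with the normal-reference p-value
   `p_a = 2(1 - Phi(|a_hat|/se))`, as is conventional at these sample
   sizes (the t-reference differs negligibly for n in the hundreds).

4. **Joint-significance (intersection–union) test.**  `P*_j =
   max(p_a, p_b)`; mediator `j` is declared significant when both
   components fall below `alpha = 0.05`.  Because the null of "no
   mediation" is the union of two nulls, the max-p rule is level-valid
   (conservative when both paths are null).  No multiplicity correction is
   applied by default, matching the procedure being implemented;
   Bonferroni/Benjamini–Hochberg are available as options.

Effect decomposition reports `ab = a_hat * b_hat` and the percent of total
effect `|ab| / |c_hat| * 100` against the marginal total-effect estimate
`c_hat`; absolute values are used so that a positive indirect effect
against a negative total effect still yields a meaningful share.

## The comparator (MCP selection + refit)

The baseline pipeline shares the SIS step, then: MCP-penalized outcome
model (selection), ordinary unpenalized refit of `Y` on `X` plus the
survivors (Wald p-values `p_b`), the same a-path OLS, and the same max-p
rule.  MCP concavity is `gamma = 3`; `lambda` minimizes BIC over a 50-point
geometric grid (two decades below the data-driven maximum).  Refit
p-values ignore the selection step — the comparator is reproduced as
specified, not repaired.  Survivorship under strong mediator correlation is
the comparator's known weakness: when several correlated mediators carry
signal, MCP tends to keep one representative per cluster, and a dropped
true mediator can never be declared significant.

## Numerical choices

* **One coordinate-descent kernel.**  Every L1/MCP solve (coefficient
  LASSO, nodewise regressions, scaled-LASSO iterations, MCP paths) runs
  through a single Gram-based penalized coordinate descent
  (`hdma._solvers`, numba-compiled): minimize
  `0.5 b'Hb - q'b + sum_j penfac_j P(b_j; lambda, gamma)` with the firm
  threshold (`gamma = inf` gives soft thresholding / LASSO).  Working on
  `H = X'X/n` makes refits, cross-validation paths and reweighting cheap.
  Convergence: max coefficient change below 1e-9 (1e-10 for MCP), capped
  at 1e5 passes.

* **Logistic fits.**  Proximal Newton (IRLS): each step solves the
  penalized weighted least-squares subproblem exactly; coefficient change
  below 1e-8 stops.  For MCP the nonconvex penalty can make plain IRLS
  cycle between active sets, so a majorize–minimize fallback with the
  global curvature bound `w <= 1/4` (monotone descent) takes over when
  IRLS has not settled in 40 steps.  MCP's concavity is rescaled by the
  coordinate curvature (adaptive rescaling) so each univariate update
  remains convex at `gamma = 3`.

* **Penalty levels.**  Continuous outcome model: 10-fold cross-validation
  (contiguous folds — fully deterministic) over a 12-point geometric grid.
  Binary outcome model: the plug-in rate `lambda = 0.5 sqrt(log p / n)`.
  The switch away from CV for the binary family is a calibration decision
  made on null simulations: the prediction-optimal penalty is too small
  for inference, leaving a near-unpenalized fit whose de-sparsified
  p-values inherit the moderate-dimension inflation of the logistic MLE
  (null rejection ~0.10 instead of 0.05 at `n = 300`, `d = 53`).  With the
  plug-in rate the same nulls reject at 0.03–0.05 and power at the design's
  signal sizes is unchanged.  CV remains available (`lambda_="cv"`).
  Nodewise penalties default to `0.25 sqrt(2 log p / n)` per column
  (scaled by the column's dispersion); per-column 10-fold CV is available
  (`nodewise_lambdas="cv"`) but costs two orders of magnitude more inside
  Monte-Carlo loops and changed no conclusion when checked.

* **Finite-sample dispersion.**  The logistic sandwich variance divides by
  `n` while the debiasing projection effectively spends `p + 1` degrees of
  freedom, and with `d = n / log n` retained mediators `p/n` is not small.
  Logistic standard errors are therefore inflated by
  `sqrt(n / (n - p - 1))` (capped at `sqrt(2)`).  The linear family needs
  no such factor: its scaled-LASSO noise estimate is computed from
  penalized residuals and its global-null p-values are already
  KS-uniform, which the test suite verifies.

* **Degenerate inputs.**  Constant mediator columns score zero in the
  screen (with a warning) rather than failing; exactly collinear columns
  raise a degeneracy error naming the column; constant responses and
  constant exposures are rejected up front; samples are aligned across
  input files by ID intersection and missing values are a hard error (no
  imputation).

## The synthetic-data generator

The generator reproduces the simulation design used throughout the
package's validation: exposure `X ~ Bernoulli(0.74)` (the marginal
frequency of a binary lifestyle exposure in a case–control methylation
study); mediators `M_i ~ MVN(theta' + a X_i, Sigma)` with `theta' = 1` and
AR(1) correlation `Sigma_st = rho^|s-t|`, `rho` in {0, 0.8}; binary outcome
`Y_i ~ Bernoulli(expit(-4.5 + c' X_i + sum_j b_j M_ij))`.  The first eight
entries of `b` are `(0.8, 0.7, 0.6, 0.5, 0, 0, 0.5, 0.5)` and of `a` are
`(0.35, 0.25, 0.35, 0.55, 0.55, 0.55, 0, 0)`; all remaining entries are
zero.  Mediators 1–4 are true mediators; 5–6 are nulls of the `a != 0,
b = 0` kind, 7–8 of the `a = 0, b != 0` kind — the two null kinds are
distinguishable from the config's coefficient vectors.  `c' = 0` gives
complete mediation (total effect 0.94), `c' = 0.5` partial mediation
(1.44).

MVN sampling uses the exact AR(1) recursion `e_1 = z_1`,
`e_j = rho e_{j-1} + sqrt(1-rho^2) z_j`, which equals the Cholesky-factor
sampler (asserted in the tests) at `O(nk)` cost.  A continuous-outcome
family (`eta + N(0,1)` noise) exists to exercise the linear inference
path.

What the generator does **not** emulate: methylation beta-value marginals
(mediators are homoscedastic Gaussians), batch or plate effects, cell-type
composition, covariate confounding, or realistic genomic correlation
beyond AR(1).  Passing the Monte-Carlo suite therefore demonstrates
correctness of the statistical machinery under the stated model, not
robustness to real-data artefacts.

## Monte-Carlo harness

`run_power_study` evaluates per-mediator rejection rates over replications
of generate → test.  Replication seeds derive from
`(seed_base, cell index, replication)` via `SeedSequence`, so results are
independent of worker count and execution order, and both methods are
evaluated on identical datasets within a cell (paired comparison — the
published study compares marginal rates, so pairing only reduces the
variance of the difference).  Mediators not retained by SIS count as
non-rejections.  Failed replications (e.g. separation) are excluded from
the denominator with a reported count; more than 2% failures flags the
cell.  The default is 200 replications per cell — power and type-I rates
are then resolved to a Monte-Carlo standard error of at most 0.035, enough
to compare against reference values at the 3-se level — with `--reps`
available for finer resolution.

## Known limitations

* Logistic de-sparsified inference at `d = n/log n` sits in a
  moderate-dimension regime; despite the dispersion correction, nulls that
  are strongly exposure-associated (`a != 0, b = 0`) reject at ~0.07–0.09
  under `rho = 0.8` rather than 0.05 — the same mild inflation the
  reference results show for those cells.
* The a-path and b-path tests are treated as independent by the max-p
  rule; no attempt is made to exploit their joint distribution, and the
  max-p test is conservative for doubly-null mediators.
* Post-selection optimism of the comparator's refit p-values is inherent
  to that pipeline and deliberately not corrected.
* Under strong correlation the comparator's per-mediator power depends on
  which member of a correlated cluster MCP happens to keep — a
  tie-breaking decision sensitive to solver details (update order,
  concavity rescaling, grid).  Totals across a cluster are stable across
  such choices; single-mediator rates can shift by several points.
* No exposure–mediator interactions, multiple exposures, or
  causal-sensitivity analyses.
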
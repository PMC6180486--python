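# Methods

## Model

`mtpen` fits L1/L2-penalized ("elastic net") logistic regression in which
features belong to groups — in the motivating application, molecular
platforms such as gene expression and DNA methylation — and each group
receives its own overall penalty strength. For a binary outcome
$y_i \in \{0,1\}$ and a partitioned feature vector
$x_i = (x_i^{(1)}, x_i^{(2)})$, the two-penalty problem is

$$
\min_{\beta_0, \beta} \; -\tfrac{1}{n}\,\ell(\beta_0, \beta)
 + \lambda_1 N(\beta^{(1)}) + \lambda_2 N(\beta^{(2)}),
\qquad
N(\beta) = \sum_j \Big[ (1-\alpha)\tfrac{1}{2}\beta_j^2 + \alpha|\beta_j| \Big],
$$

where $\ell$ is the logistic log-likelihood and $\alpha \in [0,1]$ the
lasso/ridge mixing weight. The intercept is never penalized. Writing
$\lambda = \lambda_1$ and $\kappa = \lambda_2/\lambda_1$, the problem is
equivalent to a single-penalty elastic net with per-feature penalty
factors $w = (1,\dots,1,\kappa,\dots,\kappa)$:

$$
\lambda_1 N(\beta^{(1)}) + \lambda_2 N(\beta^{(2)}) = \lambda\, N_w(\beta),
\qquad
N_w(\beta)=\sum_j w_j\Big[(1-\alpha)\tfrac12 \beta_j^2 + \alpha|\beta_j|\Big].
$$

$\kappa = 1$ recovers the ordinary elastic net; $\kappa < 1$ penalizes the
first group relatively more. The ridge term carries the $\tfrac12$
factor, matching the convention of the standard coordinate-descent
solvers for this family; we verified coefficient-level agreement with
`glmnet` (penalty factors rescaled to its sum-to-$p$ convention) to below
$10^{-8}$ during development.

The loss is scaled by $1/n$ so that useful $\lambda$ values are stable in
the sample size.

## Solver

The solver is IRLS (iteratively reweighted least squares) around the
logistic loss with cyclic coordinate descent and soft-thresholding on the
weighted least-squares subproblems, using warm starts and an active set:

- Coordinate update for feature $j$ with IRLS weights $v_i$ and working
  residual $r_i$:
  $\beta_j \leftarrow S\!\big(\tfrac1n\sum_i v_i x_{ij} r_i + a_j\beta_j,\;
  \lambda\alpha w_j\big) / \big(a_j + \lambda(1-\alpha)w_j\big)$ with
  $a_j = \tfrac1n\sum_i v_i x_{ij}^2$ and $S$ the soft-threshold map.
- Only active (currently nonzero or previously admitted) features are
  cycled. After the active-set problem converges, the full gradient of the
  logistic loss is scanned; any feature violating its KKT condition joins
  the active set and the point is re-solved. When violators are found, all
  features within 75% of their L1 threshold are admitted too — this
  reduces the number of full scans and cannot change the solution, since
  every returned fit must pass the final full KKT check.
- A fit is declared converged only when the full KKT residual of the
  logistic problem is below tolerance; non-convergence is flagged on the
  result, never silent.

Numerical choices (all overridable per call):

| constant | default | role |
| --- | --- | --- |
| inner CD tolerance | 1e-7 | max absolute coefficient change per cycle |
| IRLS objective tolerance | 1e-8 | relative penalized-objective change |
| KKT tolerance | 1e-6 | convergence certificate on the full gradient |
| IRLS weight floor | 1e-5 | guards $p_i(1-p_i)$ near 0/1 (quasi-separation) |
| max coordinate cycles | 1e5 | hard budget per fit |
| IRLS iterations per active-set round | 10 | near saturation the objective stalls; returning to the full KKT check early is both faster and safer than iterating a stale quadratic approximation |

Features are centered and scaled to unit population variance internally
by default; coefficients are reported on the original scale.
Zero-variance columns are left at coefficient zero. Penalty factor
$w_j = 0$ is allowed (an unpenalized feature) and such features are
excluded from the $\lambda$ entry-point maximum
$\lambda_{\text{entry}} = \max_j |x_j^\top(y-\bar y)| / (n\,\alpha\,w_j)$,
above which the fitted model is exactly intercept-only. $\alpha = 0$ has
no finite entry point and is rejected by the path builder; a caller who
wants pure ridge must supply an explicit $\lambda$ grid.

Regularization paths are log-spaced from $\lambda_{\text{entry}}$ down to
a fraction of it, warm-starting each fit from the previous one. When the
$(\kappa, \lambda)$ grid is traversed during cross-validation, the path
for each $\kappa$ warm-starts point-wise from the neighbouring $\kappa$'s
solutions; warm starts affect iteration counts only, since every fit is
KKT-certified.

## Tuning protocol

Stratified $k$-fold cross-validation with AUC as the figure of merit:

- Folds preserve the class ratio to within one sample and are identical
  across all $\kappa$ values, so comparisons between ratios are paired.
- For each $\kappa$, the $\lambda$ path is derived from the *full*
  training data at that $\kappa$; fold-level models are fitted at exactly
  those $\lambda$ values.
- Cell score: mean of per-fold validation AUCs (not pooled predictions);
  its standard error is $\mathrm{sd}(\text{fold AUCs})/\sqrt{\#\text{folds}}$.
  A single-class validation fold has undefined AUC and is dropped from
  the mean with a warning.
- $(\kappa_{\max}, \lambda_{\max})$ is the global argmax of the mean-AUC
  surface. Ties break toward $\kappa$ closest to 1 (the least
  differential penalization consistent with the data), then toward the
  larger $\lambda$ (the sparser model).
- The parsimony rule sets $\lambda_{1se}$ to the largest $\lambda$ on the
  winning $\kappa$'s path whose mean AUC is within one standard error of
  the maximum.

Defaults: $\kappa \in \{0.05, 0.10, \dots, 1.50\}$, 50 $\lambda$ values
down to $10^{-2}\lambda_{\text{entry}}$, $\alpha = \tfrac12$. The
simulation protocol uses 10-fold CV; the real-data pipeline defaults to
5-fold CV repeated 10 times, which suits smaller minority classes.

## Simulation study

`preset_scenarios()` returns seven presets sharing $n = 200$ samples and
$p_1 = p_2 = 250$ features per platform, with $q_j$ informative features
per platform at common effect sizes $\beta_j$, intercept 0 (expected
class balance), and features drawn from $N(0, \Sigma)$ with unit
variances. In the correlated settings the first $r_j$ informative
features of each platform are equicorrelated at $\rho_j$ and correlated
at $\rho_{12}$ with the counterpart set (all $r_1 \times r_2$ cross
pairs), all other covariances zero. Only the $(r_1{+}r_2)$-sized block
needs a covariance factor — an eigendecomposition factor, so exactly
singular blocks are tolerated — and the remaining features are
independent standard normals, which gives the same distribution as
sampling the full $\Sigma$. The PSD check reports the offending
eigenvalue when parameters are inconsistent.

Placement of informative (first $q_j$ indices of each block) and
correlated (first $r_j$ of those) features is a fixed convention; under
exchangeability of the remaining coordinates any placement is
distributionally equivalent.

Replicate experiments draw *paired* independent training and test sets
per replicate. Replicate seeds derive from a master seed and the
replicate index only (counter-based `SeedSequence`), so every $\kappa$ —
and every setting of a parameter sweep — is evaluated on common random
numbers, and any replicate can be re-run in isolation. A degenerate
single-class outcome draw is resampled with an incremented sub-seed and
logged.

What the generator emulates: group-structured sparse signals, block
correlation within and across platforms, pre-standardized features. What
it does not: heavy-tailed or skewed measurements, platform-specific
missingness, batch effects, and measurement-scale differences between
platforms — so passing tests show correct recovery of the *model's*
behavior, not robustness to those real-data complications (the real-data
pipeline standardizes internally, which addresses scale but not the
rest).

## Experiment summaries

Per scenario the runner reports, for every $\kappa$: mean test AUC with
its standard error across replicates, accuracy at the 0.5 threshold
(appropriate for the balanced design), and feature-selection sensitivity
and specificity against the generating truth ("selected" means an exactly
nonzero coefficient — coordinate descent produces exact zeros). The
optimal ratio is reported two ways: the argmax of the mean AUC curve
(table-style), and the mean of per-replicate argmax ratios with its
standard error (sweep-figure-style); both are exported because summary
tables and sweep figures conventionally use different estimators, and
the two have complementary failure modes. On a near-flat AUC curve
(e.g. equal informative counts in both platforms) the curve argmax can
sit anywhere on a plateau spanning several grid steps even at hundreds
of replicates, while the replicate mean stays stable; conversely, for
optima near the edge of the ratio grid the replicate mean is pulled
toward the grid interior (the per-replicate argmax distribution is
truncated on one side), while the curve argmax remains sharp.
Failed replicates are logged and excluded, and the run aborts if more
than 10% fail.

## Desk-scale protocol

Published-scale runs use 200 replicates per scenario. The package's
desk-scale protocol (`simulation_grid()`, used by the test suite and
`scripts/acceptance.py`) uses 50 replicates, a 30-point $\lambda$ path
down to $0.05\,\lambda_{\text{entry}}$, and fold-level solver tolerances
of 1e-5 (coordinate changes) / 1e-4 (KKT) — the cross-validated AUC
ranking is insensitive at this level, and the models actually evaluated
on test data are always refitted at the tight default tolerances. With
these sizes one scenario takes roughly 1.5 s per replicate on a single
core. The selected $\lambda$ sits in the interior of the 30-point path
throughout, and the recovered optimal ratios match the published values
to the grid resolution.

## Known limitations

- Binary outcomes only; no Cox, multinomial or Gaussian families.
- Convex elastic-net penalty only; no SCAD/MCP.
- Exhaustive grid search over $(\kappa, \lambda)$; cost grows
  exponentially with the number of platforms (two-platform presets ship,
  the types accept more groups).
- No screening rules beyond the active-set strategy; dense inputs only.
- The $\lambda_{1se}$ rule uses the CV surface's own standard errors;
  with very few folds the band is noisy and the rule errs toward
  sparser models.
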
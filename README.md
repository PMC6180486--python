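# mtpen — multi-tuning-parameter elastic net logistic regression

When building a classifier from several molecular platforms at once —
say gene expression plus DNA methylation — the standard approach
concatenates all features and applies one elastic-net penalty to
everything. That forces a common degree of shrinkage even though
platforms typically differ in how many of their features are predictive
and how strong those effects are, so subtler signals in one platform can
be shrunk away entirely by the penalty level the other platform needs.

`mtpen` fits elastic-net logistic regression with a **separate penalty
strength per platform**. For two platforms the objective is

    min over (b0, beta):  -(1/n) * loglik(b0, beta)
                          + lambda1 * N(beta_platform1)
                          + lambda2 * N(beta_platform2)

with `N(b) = sum_j [ (1-alpha)/2 * b_j^2 + alpha * |b_j| ]`. This is
solved as a weighted elastic net with penalty factors 1 for platform 1
and `kappa = lambda2/lambda1` for platform 2, overall strength
`lambda = lambda1`. `kappa = 1` is the ordinary elastic net. Both
`kappa` and `lambda` are tuned by stratified k-fold cross-validated AUC
with the one-standard-error parsimony rule for `lambda`.

The package contains:

- a weighted elastic-net logistic solver (IRLS + coordinate descent with
  active sets, warm-started paths, KKT-certified convergence),
- the cross-validation tuning machinery (paired folds across `kappa`,
  AUC surfaces, 1-SE rule),
- a synthetic-data generator for two-platform studies (sparse logistic
  truth, block-correlated Gaussian features),
- evaluation metrics (Mann-Whitney AUC, accuracy, selection
  sensitivity/specificity against the generating truth),
- an experiment runner and `mtpen` command-line interface for replicate
  studies, parameter sweeps and user-supplied CSV data.

Audience: statisticians and computational biologists doing multi-omic
sample classification, and anyone who wants a reproducible testbed for
differential-shrinkage penalized regression.

## Worked example

Simulate a two-platform dataset in which platform 1 carries 5 informative
features of effect 0.6 and platform 2 carries 20 of effect 0.8 (the
first preset scenario), then tune `(kappa, lambda)` on it:

```sh
mtpen simulate --preset scenario1 --seed 7 --out demo/
mtpen tune --features demo/scenario1_features.csv \
           --outcome demo/scenario1_outcome.csv \
           --platforms demo/scenario1_platforms.csv \
           --seed 1 --out demo/tuned/
```

which prints

```
kappa_max=0.25 lambda_1se=0.1248 CV AUC=0.721
```

The selected ratio is well below 1: with fewer informative features in
platform 1, the tuner penalizes platform 1 relatively more, exactly the
regime differential shrinkage is designed for. (On a single dataset the
selected ratio is itself noisy — the replicate experiment below is the
stable summary.) `demo/tuned/cv_surface.csv`
holds the full per-fold AUC surface over the `(kappa, lambda)` grid and
`cv_selection.csv` the selected penalties.

The same experiment at replicate scale (50 paired train/test draws),
from Python:

```python
from mtpen import ExperimentConfig, run_scenario, simulation_grid

summary = run_scenario(ExperimentConfig(
    scenario="scenario1", n_replicates=50,
    grid=simulation_grid(), master_seed=20250925,
))
print(summary.optimal_kappa)                       # 0.55
print(round(summary.mean_auc.max(), 3))            # 0.736  (at kappa*)
print(round(summary.mean_auc[summary.kappas == 1.0][0], 3))  # 0.697 (standard EN)
```

The mean test AUC at the optimal ratio (0.55) beats the standard elastic
net (`kappa = 1`) by about 0.04 — the headline benefit of differential
penalization when the platforms differ in their number of informative
features. Scenario presets `scenario1` .. `scenario7` cover different
effect sizes, sparsity patterns and correlation structures;
`mtpen sweep` varies one generative factor at a time; `mtpen user-data`
runs the repeated stratified 80/20-split pipeline on your own CSV files
(samples x features matrix, a two-column outcome file, and a
feature-to-platform annotation).

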
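# Methods

This note records the models implemented in `survstack`, the assumptions they
make, the numerical choices that were genuinely open, and what the synthetic
cohorts do and do not establish about real data.

## Survival framework

All learners target the same estimand: a per-patient relative log-risk
`r(X)` under proportional hazards, `h(t|X) = h0(t)·exp(r(X))`. Because every
metric in scope (Harrell's C, Uno's C) depends only on the ranking of risks,
the baseline hazard is never estimated and no learner predicts survival
curves. Time-varying covariates, competing risks and stratified baselines
are out of scope.

The shared loss is the Cox log partial likelihood
`Σᵢ δᵢ [rᵢ − log Σ_{l∈R(Tᵢ)} exp(r_l)]` with risk set
`R(t) = {l : T_l ≥ t}`. Tied event times use the **Breslow** convention
everywhere by default (every tied event sees the full risk set); Efron's
correction is available through `ties="efron"` in
`cox_partial_likelihood` and `newton_cox`.

## Base learners

| kind | fitting | backend |
|---|---|---|
| `cox` | Newton–Raphson on the partial likelihood, step halving, SEs from the observed information | this package |
| `pretrained_linear` | none — applies published coefficients `βX` as-is | this package |
| `coxnet` | elastic net `log PL − λ(α‖β‖₁ + ½(1−α)‖β‖₂²)`, covariates standardised internally; `α=1` lasso, `α=0` ridge | scikit-survival coordinate descent for `α>0`; own ridge Newton for the smooth `α=0` limit |
| `gb_cox` | stage-wise regression trees on the partial-likelihood gradient, `r̂(X)=Σ ρ f_k(X)`, shrinkage ρ=0.1 fixed, no subsampling | scikit-survival |
| `rsf` | log-rank splits, ensemble cumulative-hazard risk; terminal-node size controls in samples | scikit-survival |
| `deepsurv` | feed-forward net minimising `−log PL + λ‖W‖²` | this package (numpy MLP) |
| `ae_cox` | autoencoder compression, then Cox on the codes: `h(t|Z)=h0(t)·exp(Zβ)` | this package (numpy MLP + own Newton) |

Newton convergence is declared when the summed score falls below
`tol × n` (default `tol = 1e−8` per observation). If step halving stalls at
floating-point precision while the per-observation score max-norm is already
below `1e−6`, the fit is accepted: beyond that point the objective cannot be
improved in double precision and the remaining score is statistically
negligible.

**DeepSurv.** Inputs standardised; one hidden layer of 90 units with selu
activation is the tuned default (tanh available); minibatch Adam (batch 256,
lr 1e−3) on within-batch Breslow risk sets; weight decay 1e−4; a held-out
fraction (default 10%) of the training data monitors the validation partial
likelihood for early stopping with patience 10, best weights restored.

**Autoencoder.** Inputs min–max scaled to [0,1] on training ranges (frozen
into the learner, as the sigmoid decoder output requires bounded targets);
relu encoder whose final layer is the bottleneck `p`, mirror decoder with a
sigmoid output, MSE objective, Adam. Intermediate layers are kept wider than
the code (`max(2·input, 2·bottleneck, 16)`) so only the final layer
bottlenecks. Because relu codes can die under an unlucky initialisation,
training restarts from several seeds (default 4) and keeps the best
reconstruction. The downstream Cox fit on the codes uses a small ridge
(`1e−4·n`) and a relaxed tolerance because bottleneck codes can be nearly
collinear.

## Super Learner

`cv_risk_matrix` assigns balanced random folds (sizes differ by ≤1), fits
each library entry V times and concatenates held-out predictions, so every
patient's entry comes from a model that never saw their fold. Out-of-fold
columns are standardised to mean 0, SD 1 — raw base risks live on wildly
different scales, and standardisation makes the weights comparable and the
optimum better conditioned. The standardisation parameters are frozen and
re-applied at prediction time after the full-data refit of each base
learner.

`fit_sl_weights` maximises Harrell's C of `Σ α_k ĥ_k` over the box
`α ∈ [0,1]^K` with L-BFGS-B. The exact C-index is piecewise constant in α,
so the optimiser runs on a smoothed surrogate — pairwise sigmoids with
temperature `0.1 × SD` of the combined score — while candidate selection
across starting points (the uniform start plus `n_restarts` random starts,
default 20) uses the **exact** C-index. When a cohort yields more than
200,000 comparable pairs, the surrogate evaluates a seeded subsample of that
size; exact-C selection is never subsampled. The winning weights are
normalised to the simplex and entries below 1e−3 are truncated to zero and
the rest renormalised (small contributions are scaled down to zero). V
defaults to 10.

## Concordance metrics

**Harrell.** Ordered pair (i, j) is comparable iff `Tᵢ < Tⱼ` and `δᵢ=1`, or
`Tᵢ = Tⱼ` with i an event and j censored (event ranked first). Two events at
the same time are not comparable. Tied risks score 0.5. With no comparable
pairs the metric raises rather than returning 0.5.

**Uno.** Comparable pairs are strictly ordered event pairs with `Tᵢ < τ`,
weighted `Ĝ(Tᵢ⁻)⁻²`, where `Ĝ` is the Kaplan–Meier estimator of the
*censoring* survival curve (roles of event and censoring swapped) evaluated
left-continuously. τ defaults to the largest follow-up time at which `Ĝ`
is still positive; pairs that would divide by `Ĝ = 0` are dropped, and an
error is raised only if nothing remains. With zero censoring `Ĝ ≡ 1` and
Uno's C equals Harrell's exactly.

**Inference.** Percentile bootstrap over patient-level resamples (default
B = 1000, level 95%); resamples on which the metric is undefined are redrawn
and counted. Model comparison reports both the conservative CI-disjointness
rule and a two-sided paired-bootstrap p-value for `ΔC = 0` computed on
shared resample indices.

## Imputation

missForest-style: initialise missing cells with column means, visit columns
in order of increasing missingness, fit a regression forest per column on
its observed rows (default 100 trees), predict its missing cells, and
iterate (≤10 sweeps) until the normalised sum of squared changes in the
imputed cells rises, keeping the previous sweep. The forests of the last
accepted sweep are frozen into the imputer. Application to new data is a
single deterministic pass — fallback means, then the frozen forests in
training order — never a refit, and outcomes are never inputs; this is what
makes train-only imputation leakage-safe by construction. Only continuous
covariates are handled; pre-encoded binaries are imputed as continuous and
not rounded (rounding would silently invent categories).

## Synthetic cohorts

The generator emulates the shape of an EHR-derived pan-cancer cohort:
standard-normal covariates (optionally thresholded to 0/1), a true log-risk
with linear, pairwise-interaction and quadratic terms, Weibull
proportional-hazards event times by inverse transform
`T = λ_w(−log U / e^r)^{1/k}`, and independent exponential censoring whose
rate is calibrated by root-finding so the expected censored fraction matches
a target. Defaults: shape 1.2, scale ≈ 25.8 months, giving a baseline median
survival of 19 months — typical of real-world first-line oncology cohorts,
whose event fractions (∼40–70%) the censoring target covers. Missingness is
MCAR only.

What passing tests on these cohorts do **not** show: robustness to
informative censoring, to missingness that depends on observed or latent
health status, to heavy-tailed or categorical covariates, or to violations
of proportional hazards — none of which the generator produces.

## Problem sizes used in the test suite

The statistical suites run at compact but honest sizes chosen so the whole
suite completes in minutes: coefficient recovery at n = 2000 over 40 seeds;
stacking oracle recovery at n = 3000 (uncensored, 10 seeds); stacked-vs-best
out-of-fold comparison at n = 3000, V = 10, 5 seeds with small tree
ensembles (40 boosting stumps; 15 depth-≤7 forest trees); the
nonlinear-vs-linear comparison on a 4000/1000 split; bootstrap coverage over
200 cohorts of n = 300 with B = 200 against a reference concordance computed
at n = 20,000. Ensemble sizes affect absolute concordance but not the
directional claims being tested; the library defaults (e.g. 500 forest
trees, up to 1000 boosting stages) mirror common practice for production
fits.

## Known limitations

- Risk ranking only; no calibrated survival probabilities or Brier scores.
- `coxnet` coefficients are reported on the standardised scale.
- The L-BFGS-B weight fit optimises a surrogate; with near-duplicate
  columns the split of weight among them is arbitrary (the combined ranking
  is not).
- The numpy neural components are CPU-bound and intended for tabular widths
  (tens of covariates), not image/sequence scale.
- `rsf` terminal-node control is in samples (backend limitation), standing
  in for a minimum count of unique events per node.
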
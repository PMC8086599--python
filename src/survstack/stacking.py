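"""Survival Super Learner: out-of-fold risk stacking with a C-index objective.

The procedure: split the training data into V folds; for each base learner k
and fold v, fit on the complement and predict the held-out fold; concatenate
to the out-of-fold risk column h_k.  The stacked score is the convex
combination ``h_SL(x) = sum_k alpha_k * h_k(x)``, with the weights chosen to
maximise Harrell's C-index of the combined out-of-fold score via bounded
L-BFGS-B.

Because the exact C-index is piecewise constant in alpha, the optimizer runs
on a smoothed concordance surrogate (pairwise sigmoid with a temperature tied
to the spread of the combined scores) while candidate selection between
restarts uses the exact C-index.  Out-of-fold columns are standardised (mean
0, SD 1) before weight fitting, since raw base-learner risks live on wildly
different scales; the standardisation parameters are frozen into the model
and re-applied at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .datasets import FeatureSet, SurvivalDataset, survival_y
from .learners import FittedLearner, LearnerSpec, fit_learner, predict_risk
from .metrics import harrell_cindex

__all__ = [
    "RiskMatrix",
    "StackedModel",
    "SuperLearner",
    "cv_risk_matrix",
    "fit_sl_weights",
    "fit_super_learner",
    "predict_stacked",
]

#: cap on comparable pairs evaluated by the smoothed surrogate (seeded subsample)
_MAX_PAIRS = 200_000
#: weights below this after normalisation are scaled down to zero
_TRUNCATE = 1e-3


@dataclass
class RiskMatrix:
    """n x K matrix of standardised out-of-fold risks plus bookkeeping."""

    values: np.ndarray
    learner_specs: list[LearnerSpec]
    fold_assignment: np.ndarray
    col_means: np.ndarray
    col_sds: np.ndarray
    standardized: bool = True

    @property
    def n_learners(self) -> int:
        return self.values.shape[1]


@dataclass
class StackedModel:
    """Fitted Super Learner: simplex weights over refit base learners."""

    weights: np.ndarray
    base_learners: list[FittedLearner]
    col_means: np.ndarray
    col_sds: np.ndarray
    feature_names: tuple[str, ...]


def _fold_assignment(n: int, V: int, rng) -> np.ndarray:
    """Balanced random fold ids in 0..V-1 (sizes differ by at most one)."""
    ids = np.arange(n) % V
    return ids[rng.permutation(n)]


def cv_risk_matrix(
    specs: list[LearnerSpec],
    ds: SurvivalDataset,
    feature_set: FeatureSet | None = None,
    V: int = 10,
    seed: int = 0,
) -> RiskMatrix:
    """Build the out-of-fold risk matrix: every patient predicted exactly once
    per learner, by a model fitted without that patient's fold."""
    if V < 2:
        raise ValueError("V must be at least 2")
    n = ds.n_patients
    if n < V:
        raise ValueError(f"need at least V={V} patients, got {n}")
    rng = np.random.default_rng(seed)
    folds = _fold_assignment(n, V, rng)
    K = len(specs)
    values = np.full((n, K), np.nan)
    for k, spec in enumerate(specs):
        for v in range(V):
            val = folds == v
            train = ~val
            try:
                m = fit_learner(spec, ds.subset(train), feature_set,
                                seed=seed + 1000 * k + v)
                values[val, k] = predict_risk(m, ds.subset(val).matrix(feature_set))
            except Exception as err:
                raise RuntimeError(
                    f"learner {spec.label()} failed on fold {v}: {err}"
                ) from err
    means = values.mean(axis=0)
    sds = values.std(axis=0)
    sds[sds == 0.0] = 1.0
    return RiskMatrix((values - means) / sds, list(specs), folds, means, sds)


def _smoothed_concordance(scores, pair_i, pair_j):
    diff = scores[pair_i] - scores[pair_j]
    sd = scores.std()
    temp = 0.1 * sd if sd > 0 else 1.0
    return float(np.mean(1.0 / (1.0 + np.exp(-diff / temp))))


def _comparable_pairs(times, events, rng):
    """Index arrays (i, j) of Harrell-comparable ordered pairs, subsampled."""
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    ii, jj = [], []
    n = len(t)
    for pos in range(n):
        if e[pos] != 1:
            continue
        # strictly later times, plus equal-time censored partners
        start = np.searchsorted(t, t[pos], side="right")
        js = np.arange(start, n)
        tied = np.flatnonzero((t == t[pos]) & (e == 0))
        js = np.concatenate([js, tied])
        if js.size:
            ii.append(np.full(js.size, order[pos]))
            jj.append(order[js])
    if not ii:
        raise ValueError("no comparable pairs: concordance undefined")
    pi = np.concatenate(ii)
    pj = np.concatenate(jj)
    if len(pi) > _MAX_PAIRS:
        keep = rng.choice(len(pi), size=_MAX_PAIRS, replace=False)
        pi, pj = pi[keep], pj[keep]
    return pi, pj


def fit_sl_weights(
    rm: RiskMatrix | np.ndarray,
    times,
    events,
    n_restarts: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """C-index-maximising convex weights over the out-of-fold risk columns.

    L-BFGS-B with per-coordinate bounds [0, 1] and a numerically
    differentiated smoothed-concordance objective, started from the uniform
    point plus ``n_restarts`` random nonnegative points; the candidate with
    the best exact Harrell C wins.  The result is normalised onto the simplex
    and weights below 1e-3 are truncated to zero (then renormalised).
    """
    H = rm.values if isinstance(rm, RiskMatrix) else np.asarray(rm, dtype=float)
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events).astype(int).ravel()
    n, K = H.shape
    if K == 0:
        raise ValueError("no learner columns")
    if K == 1:
        harrell_cindex(H[:, 0], times, events)  # raises if no comparable pairs
        return np.array([1.0])
    rng = np.random.default_rng(seed)
    pair_i, pair_j = _comparable_pairs(times, events, rng)

    def neg_smoothed(alpha):
        return -_smoothed_concordance(H @ alpha, pair_i, pair_j)

    starts = [np.full(K, 1.0 / K)]
    starts += [rng.uniform(0.0, 1.0, size=K) for _ in range(n_restarts)]
    best_alpha, best_c = None, -np.inf
    for x0 in starts:
        res = minimize(
            neg_smoothed, x0, method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * K,
            options={"maxiter": 200, "eps": 1e-3},
        )
        cand = res.x
        if cand.sum() <= 0:
            continue
        c = harrell_cindex(H @ cand, times, events)
        if c > best_c:
            best_alpha, best_c = cand, c
    if best_alpha is None or best_alpha.sum() <= 0:
        best_alpha = np.full(K, 1.0 / K)
    alpha = best_alpha / best_alpha.sum()
    small = alpha < _TRUNCATE
    if small.any() and not small.all():
        alpha[small] = 0.0
        alpha /= alpha.sum()
    return alpha


def fit_super_learner(
    specs: list[LearnerSpec],
    ds: SurvivalDataset,
    feature_set: FeatureSet | None = None,
    V: int = 10,
    seed: int = 0,
    n_restarts: int = 20,
) -> StackedModel:
    """Full Super Learner: CV risk matrix, weight fit, full-data refit."""
    rm = cv_risk_matrix(specs, ds, feature_set, V=V, seed=seed)
    alpha = fit_sl_weights(rm, ds.times, ds.events, n_restarts=n_restarts, seed=seed)
    base = [fit_learner(s, ds, feature_set, seed=seed + 1000 * k)
            for k, s in enumerate(specs)]
    names = tuple(feature_set.covariate_names) if feature_set is not None else tuple(ds.covariate_names)
    return StackedModel(alpha, base, rm.col_means, rm.col_sds, names)


def predict_stacked(sm: StackedModel, covariates) -> np.ndarray:
    """Stacked risk: standardise each base prediction (frozen CV parameters)
    and return the weighted sum."""
    cols = [m.predict(covariates) for m in sm.base_learners]
    H = (np.column_stack(cols) - sm.col_means) / sm.col_sds
    return H @ sm.weights


class SuperLearner(BaseEstimator):
    """sklearn-style wrapper around the stacking procedure.

    Parameters mirror :func:`fit_super_learner`; ``fit(X, y)`` takes the
    structured (event, time) ``y``.  Fitted attributes: ``weights_``,
    ``base_learners_``, ``risk_matrix_``.
    """

    def __init__(self, specs=None, V: int = 10, n_restarts: int = 20,
                 random_state: int = 0):
        self.specs = specs
        self.V = V
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        times = np.asarray(y["time"], dtype=float)
        events = np.asarray(y["event"]).astype(int)
        names = [f"x{j + 1}" for j in range(X.shape[1])]
        ds = SurvivalDataset(X, times, events, names)
        specs = self.specs if self.specs is not None else [LearnerSpec("cox", {})]
        rm = cv_risk_matrix(specs, ds, None, V=self.V, seed=self.random_state)
        self.risk_matrix_ = rm
        self.weights_ = fit_sl_weights(rm, times, events,
                                       n_restarts=self.n_restarts,
                                       seed=self.random_state)
        self.base_learners_ = [
            fit_learner(s, ds, None, seed=self.random_state + 1000 * k)
            for k, s in enumerate(specs)
        ]
        self.model_ = StackedModel(self.weights_, self.base_learners_,
                                   rm.col_means, rm.col_sds, tuple(names))
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        return predict_stacked(self.model_, np.asarray(X, dtype=float))
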
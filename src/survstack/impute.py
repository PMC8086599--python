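"""Iterative random-forest imputation with a frozen, persistable imputer.

The scheme is the classic iterative-forest one: initialise missing cells with
column means, visit covariates in order of increasing missingness, fit a
regression forest for each on the rows where it is observed (using all other
columns in their current state) and predict its missing cells; repeat until
the normalised change between successive iterations rises, keeping the
previous iteration's values, or a maximum iteration count is reached.

Leakage safety is the point of the frozen-model contract: the forests are fit
on the training covariates only (never on outcomes), saved, and applied to
new data in a single deterministic pass — so test-set imputation can never
peek at test-set outcomes or refit on test-set values.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestRegressor

import joblib

__all__ = ["IterativeForestImputer", "fit_imputer", "apply_imputer",
           "save_imputer", "load_imputer"]


class IterativeForestImputer(BaseEstimator, TransformerMixin):
    """missForest-style imputer with frozen apply-time forests.

    Parameters
    ----------
    max_iterations : int
        Cap on training sweeps over the missing columns.
    n_trees : int
        Trees per regression forest.
    random_state : int
        Seeds every forest; identical inputs and seed give bit-identical
        completions.

    Only continuous covariates are handled (pre-encoded binary columns are
    imputed as continuous and not rounded).
    """

    def __init__(self, max_iterations: int = 10, n_trees: int = 100,
                 random_state: int = 0):
        self.max_iterations = max_iterations
        self.n_trees = n_trees
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("covariate matrix must be 2-dimensional")
        n, p = X.shape
        miss = np.isnan(X)
        fully_missing = np.flatnonzero(miss.all(axis=0))
        if fully_missing.size:
            raise ValueError(
                f"covariate column(s) {fully_missing.tolist()} are 100% missing; cannot impute"
            )
        self.n_features_in_ = p
        self.fallbacks_ = np.nanmean(X, axis=0)
        cols = np.flatnonzero(miss.any(axis=0))
        # visit in order of increasing missingness
        self.visit_order_ = cols[np.argsort(miss[:, cols].mean(axis=0), kind="stable")]
        self.forests_ = {}
        self.n_iterations_ = 0
        if cols.size == 0:
            return X.copy()

        filled = X.copy()
        filled[miss] = np.take(self.fallbacks_, np.nonzero(miss)[1])
        prev_filled = filled.copy()
        prev_forests: dict[int, RandomForestRegressor] = {}
        prev_gamma = np.inf
        for it in range(1, self.max_iterations + 1):
            forests: dict[int, RandomForestRegressor] = {}
            new = filled.copy()
            for j in self.visit_order_:
                obs = ~miss[:, j]
                other = np.delete(np.arange(p), j)
                rf = RandomForestRegressor(
                    n_estimators=self.n_trees,
                    random_state=self.random_state + int(j),
                )
                rf.fit(new[obs][:, other], X[obs, j])
                new[miss[:, j], j] = rf.predict(new[miss[:, j]][:, other])
                forests[int(j)] = rf
            num = float(np.sum((new[miss] - filled[miss]) ** 2))
            den = float(np.sum(new[miss] ** 2))
            gamma = num / den if den > 0 else 0.0
            if gamma > prev_gamma:
                # change criterion rose: keep the previous iteration
                filled, forests = prev_filled, prev_forests
                self.n_iterations_ = it - 1
                break
            prev_filled, prev_forests, prev_gamma = new.copy(), forests, gamma
            filled = new
            self.n_iterations_ = it
        self.forests_ = prev_forests  # first sweep is always accepted, so non-empty
        return filled

    # -- frozen application ------------------------------------------------

    def transform(self, X):
        """Single-pass completion of new data with the frozen forests.

        Missing cells are initialised with the training fallbacks, then the
        training-time columns are revisited in the training order and their
        missing cells overwritten by the frozen forest predictions.  Observed
        cells are never altered and no refitting occurs — outcome columns of
        the new data are never consulted.
        """
        if not hasattr(self, "fallbacks_"):
            raise RuntimeError("imputer is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} covariate columns, got {X.shape[1]}"
            )
        miss = np.isnan(X)
        out = X.copy()
        out[miss] = np.take(self.fallbacks_, np.nonzero(miss)[1])
        p = self.n_features_in_
        for j in self.visit_order_:
            mj = miss[:, int(j)]
            if not mj.any():
                continue
            other = np.delete(np.arange(p), int(j))
            out[mj, int(j)] = self.forests_[int(j)].predict(out[mj][:, other])
        return out


def fit_imputer(
    train_covariates,
    max_iterations: int = 10,
    n_trees: int = 100,
    seed: int = 0,
) -> tuple[IterativeForestImputer, np.ndarray]:
    """Fit the iterative-forest imputer; returns (imputer, completed matrix)."""
    imp = IterativeForestImputer(
        max_iterations=max_iterations, n_trees=n_trees, random_state=seed
    )
    completed = imp.fit_transform(train_covariates)
    return imp, completed


def apply_imputer(imp: IterativeForestImputer, new_covariates) -> np.ndarray:
    """Complete new data with a frozen fitted imputer (single pass)."""
    return imp.transform(new_covariates)


def save_imputer(imp: IterativeForestImputer, path) -> None:
    joblib.dump(imp, path)


def load_imputer(path) -> IterativeForestImputer:
    return joblib.load(path)
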
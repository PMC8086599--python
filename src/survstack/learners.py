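"""Base survival learners behind one fit/predict contract.

Seven kinds are supported, all producing a per-patient relative log-risk
(higher = worse prognosis, shorter expected survival):

``cox``
    Plain Cox proportional hazards, Newton-fitted partial likelihood.
``pretrained_linear``
    A published linear score applied as-is (no refitting) — the role played
    by an externally developed prognostic index such as a pan-cancer Cox
    score; the risk is simply ``beta @ X`` on named covariates.
``coxnet``
    Elastic-net penalised Cox: mixing ``alpha`` (1 = lasso, 0 = ridge) and
    penalty weight ``lam``; covariates standardised internally.
``gb_cox``
    Stage-wise gradient boosting of regression trees on the partial-likelihood
    gradient residuals (scikit-survival backend).
``rsf``
    Random survival forest with log-rank splitting; risk is the ensemble
    cumulative-hazard summary (scikit-survival backend).
``deepsurv``
    Feed-forward network trained on the Cox partial likelihood with weight
    decay, minibatch Adam and early stopping on a held-out validation split.
``ae_cox``
    Autoencoder dimensionality reduction (relu encoder, sigmoid decoder on
    min-max-scaled inputs) followed by a plain Cox model on the bottleneck
    codes Z: ``h(t|Z) = h0(t) * exp(Z beta)``.

Estimators follow scikit-learn conventions: ``fit(X, y)`` with the structured
(event, time) ``y`` produced by :func:`survstack.datasets.survival_y`,
``predict(X)`` returning the risk vector, fitted attributes with a trailing
underscore.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from ._nn import MLP, Adam, cox_risk_gradient
from .coxph import cox_partial_likelihood, newton_cox
from .datasets import FeatureSet, SurvivalDataset, survival_y
from .metrics import harrell_cindex

__all__ = [
    "LearnerSpec",
    "FittedLearner",
    "CoxPHLearner",
    "PretrainedLinearRisk",
    "CoxnetLearner",
    "GradientBoostedCox",
    "RandomSurvivalForestLearner",
    "DeepSurvLearner",
    "EncoderTransform",
    "fit_autoencoder",
    "AutoencoderCox",
    "fit_learner",
    "predict_risk",
    "grid_search",
    "default_library",
]

KINDS = ("cox", "pretrained_linear", "coxnet", "gb_cox", "rsf", "deepsurv", "ae_cox")


def _check_matrix(X, n_features=None):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("covariate matrix must be 2-dimensional")
    if np.any(np.isnan(X)):
        raise ValueError("covariate matrix contains missing cells; impute first")
    if np.any(~np.isfinite(X)):
        raise ValueError("covariate matrix contains non-finite values")
    if n_features is not None and X.shape[1] != n_features:
        raise ValueError(f"expected {n_features} covariates, got {X.shape[1]}")
    return X


def _unpack_y(y):
    y = np.asarray(y)
    return y["time"].astype(float), y["event"].astype(int)


class _RiskEstimator(BaseEstimator):
    """Shared predict plumbing: subclasses implement _fit and _risk."""

    def fit(self, X, y):
        X = _check_matrix(X)
        times, events = _unpack_y(y)
        if len(times) != X.shape[0]:
            raise ValueError("X and y length mismatch")
        self.n_features_in_ = X.shape[1]
        self._fit(X, times, events)
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = _check_matrix(X, self.n_features_in_)
        r = np.asarray(self._risk(X), dtype=float).ravel()
        if np.any(~np.isfinite(r)):
            raise ValueError("non-finite risk predictions")
        return r


class CoxPHLearner(_RiskEstimator):
    """Cox proportional hazards via Newton-Raphson on the partial likelihood.

    ``ties`` selects the Breslow (default) or Efron convention; ``penalty``
    adds an optional ridge term ``penalty/2 * ||beta||^2``.
    """

    def __init__(self, ties="breslow", penalty=0.0, tol=1e-8, max_iter=100):
        self.ties = ties
        self.penalty = penalty
        self.tol = tol
        self.max_iter = max_iter

    def _fit(self, X, times, events):
        beta, se, ll, n_iter = newton_cox(
            X, times, events, ties=self.ties, penalty=self.penalty,
            tol=self.tol, max_iter=self.max_iter,
        )
        self.coef_, self.se_, self.loglik_, self.n_iter_ = beta, se, ll, n_iter

    def _risk(self, X):
        return X @ self.coef_


class PretrainedLinearRisk(_RiskEstimator):
    """A fixed published linear score; ``fit`` validates but never re-estimates."""

    def __init__(self, coef=(), covariate_names=None):
        self.coef = coef
        self.covariate_names = covariate_names

    def _fit(self, X, times, events):
        coef = np.asarray(self.coef, dtype=float).ravel()
        if len(coef) != X.shape[1]:
            raise ValueError(
                f"pretrained coefficients have length {len(coef)}, data has {X.shape[1]} covariates"
            )
        self.coef_ = coef

    def _risk(self, X):
        return X @ self.coef_


class CoxnetLearner(_RiskEstimator):
    """Elastic-net Cox: maximise log PL - lam * (alpha*L1 + (1-alpha)/2 * L2).

    ``alpha`` is the mixing parameter (1 = lasso, 0 = ridge); ``lam`` the
    penalty weight.  Covariates are standardised internally; coefficients are
    reported on the standardised scale.  The lasso/elastic-net path is solved
    by scikit-survival's coordinate descent; the smooth ridge limit uses this
    package's penalised Newton solver.
    """

    def __init__(self, alpha=0.5, lam=0.1):
        self.alpha = alpha
        self.lam = lam

    def _fit(self, X, times, events):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("mixing alpha must lie in [0, 1]")
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0.0] = 1.0
        self.scale_ = (mean, sd)
        Z = (X - mean) / sd
        if self.alpha == 0.0:
            # smooth objective; penalty scaled by n to match the mean-log-PL
            # normalisation of the coordinate-descent backend
            beta, _, _, _ = newton_cox(
                Z, times, events, penalty=self.lam * len(times), max_iter=200
            )
            self.coef_ = beta
        else:
            from sksurv.linear_model import CoxnetSurvivalAnalysis

            model = CoxnetSurvivalAnalysis(
                alphas=[max(self.lam, 1e-10)], l1_ratio=self.alpha, fit_baseline_model=False
            )
            model.fit(Z, survival_y(times, events))
            self.coef_ = np.asarray(model.coef_).ravel()

    def _risk(self, X):
        mean, sd = self.scale_
        return ((X - mean) / sd) @ self.coef_


class GradientBoostedCox(_RiskEstimator):
    """Gradient-boosted Cox: N stage-wise depth-L trees on PL gradient residuals.

    The fitted score is ``r_GB(X) = sum_k rho * f_k(X)`` with shrinkage
    ``rho`` fixed at 0.1 and no subsampling by default.
    """

    def __init__(self, n_estimators=100, max_depth=1, learning_rate=0.1,
                 subsample=1.0, random_state=0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.subsample = subsample
        self.random_state = random_state

    def _fit(self, X, times, events):
        from sksurv.ensemble import GradientBoostingSurvivalAnalysis

        self.model_ = GradientBoostingSurvivalAnalysis(
            loss="coxph",
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            subsample=self.subsample,
            random_state=self.random_state,
        )
        self.model_.fit(X, survival_y(times, events))

    def _risk(self, X):
        return self.model_.predict(X)


class RandomSurvivalForestLearner(_RiskEstimator):
    """Random survival forest; risk = ensemble cumulative-hazard summary.

    Trees split by the log-rank criterion and grow until terminal nodes fall
    below ``min_samples_leaf`` samples (proxy for a minimum number of unique
    events per node).
    """

    def __init__(self, n_trees=500, min_samples_leaf=3, max_features="sqrt",
                 max_depth=None, random_state=0, n_jobs=None):
        self.n_trees = n_trees
        self.min_samples_leaf = min_samples_leaf
        self.max_features = max_features
        self.max_depth = max_depth
        self.random_state = random_state
        self.n_jobs = n_jobs

    def _fit(self, X, times, events):
        from sksurv.ensemble import RandomSurvivalForest

        self.model_ = RandomSurvivalForest(
            n_estimators=self.n_trees,
            min_samples_leaf=self.min_samples_leaf,
            max_features=self.max_features,
            max_depth=self.max_depth,
            random_state=self.random_state,
            n_jobs=self.n_jobs,
        )
        self.model_.fit(X, survival_y(times, events))

    def _risk(self, X):
        return self.model_.predict(X)


class DeepSurvLearner(_RiskEstimator):
    """Feed-forward Cox network: minimise -log PL(theta) + weight_decay*||W||^2.

    Inputs are standardised internally.  Training is minibatch Adam with
    within-batch risk sets (Breslow), early stopping on the held-out
    validation partial likelihood with the given patience, best weights
    restored.  The tuned default mirrors a single hidden layer with selu
    activation.
    """

    def __init__(self, n_hidden_layers=1, n_neurons=90, activation="selu",
                 weight_decay=1e-4, epochs=200, batch_size=256, lr=1e-3,
                 patience=10, validation_fraction=0.1, random_state=0):
        self.n_hidden_layers = n_hidden_layers
        self.n_neurons = n_neurons
        self.activation = activation
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _fit(self, X, times, events):
        if self.activation not in ("tanh", "selu"):
            raise ValueError("deepsurv activation must be 'tanh' or 'selu'")
        rng = np.random.default_rng(self.random_state)
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0.0] = 1.0
        self.scale_ = (mean, sd)
        Z = (X - mean) / sd
        n = len(times)

        # held-out validation split for early stopping
        n_val = max(int(round(n * self.validation_fraction)), 1) if self.validation_fraction > 0 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Zt, tt, et = Z[tr_idx], times[tr_idx], events[tr_idx]
        Zv, tv, ev = Z[val_idx], times[val_idx], events[val_idx]
        monitor = n_val > 1 and ev.sum() > 0

        sizes = [X.shape[1]] + [self.n_neurons] * self.n_hidden_layers + [1]
        acts = [self.activation] * self.n_hidden_layers + ["linear"]
        net = MLP(sizes, acts, rng)
        opt = Adam(net.W + net.b, lr=self.lr)
        best = (np.inf, net.get_weights())
        wait = 0
        for _ in range(self.epochs):
            order = rng.permutation(len(tt))
            for start in range(0, len(tt), self.batch_size):
                idx = order[start : start + self.batch_size]
                if et[idx].sum() == 0 or len(idx) < 2:
                    continue
                zs, acts_out = net.forward(Zt[idx])
                r = acts_out[-1].ravel()
                g = cox_risk_gradient(r, tt[idx], et[idx]) / len(idx)
                gW, gb = net.backward(zs, acts_out, g[:, None])
                gW = [gw + 2.0 * self.weight_decay * w for gw, w in zip(gW, net.W)]
                opt.step(gW + gb)
            if monitor:
                val_loss = -cox_partial_likelihood(net.predict(Zv).ravel(), tv, ev)
                if val_loss < best[0] - 1e-9:
                    best = (val_loss, net.get_weights())
                    wait = 0
                else:
                    wait += 1
                    if wait >= self.patience:
                        break
        if monitor and np.isfinite(best[0]):
            net.set_weights(best[1])
        self.net_ = net

    def _risk(self, X):
        mean, sd = self.scale_
        return self.net_.predict((X - mean) / sd).ravel()


class EncoderTransform:
    """A frozen encoder: min-max scaling (training ranges) + MLP to codes Z."""

    def __init__(self, net: MLP, lo: np.ndarray, span: np.ndarray):
        self._net = net
        self._lo = lo
        self._span = span

    def scale(self, X):
        return np.clip((X - self._lo) / self._span, 0.0, 1.0)

    def transform(self, X):
        X = _check_matrix(X, len(self._lo))
        return self._net.predict(self.scale(X))


def fit_autoencoder(
    X,
    encoder_depth: int = 1,
    bottleneck: int = 8,
    seed: int = 0,
    epochs: int = 300,
    batch_size: int = 128,
    lr: float = 3e-3,
    n_restarts: int = 4,
):
    """Train a reconstruction autoencoder and return the frozen encoder.

    Inputs are min-max scaled to [0, 1] (training ranges frozen into the
    transform); the encoder uses relu activations, the decoder mirrors it
    with a sigmoid output layer, and training minimises mean squared
    reconstruction error with Adam.  Intermediate layers stay wider than the
    code so only the final encoder layer bottlenecks; ``n_restarts``
    independent initialisations are trained and the best reconstruction kept
    (relu codes can die under an unlucky start).  Returns
    ``(encoder, reconstruction_mse)``.
    """
    X = _check_matrix(X)
    n, p = X.shape
    if not 1 <= bottleneck <= p:
        raise ValueError(f"bottleneck must lie in [1, {p}], got {bottleneck}")
    rng = np.random.default_rng(seed)
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0.0] = 1.0
    Z = (X - lo) / span

    hidden = max(2 * p, 2 * bottleneck, 16)
    widths = [hidden] * (encoder_depth - 1) + [bottleneck]
    enc_sizes = [p] + list(widths)
    dec_sizes = list(widths[::-1][1:]) + [p]
    sizes = enc_sizes + dec_sizes
    acts = ["relu"] * len(widths) + ["relu"] * (len(dec_sizes) - 1) + ["sigmoid"]

    best_net, best_mse = None, np.inf
    for _ in range(max(n_restarts, 1)):
        net = MLP(sizes, acts, rng)
        opt = Adam(net.W + net.b, lr=lr)
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                zs, acts_out = net.forward(Z[idx])
                err = acts_out[-1] - Z[idx]
                grad = 2.0 * err / err.size
                gW, gb = net.backward(zs, acts_out, grad)
                opt.step(gW + gb)
        mse = float(np.mean((net.predict(Z) - Z) ** 2))
        if mse < best_mse:
            best_net, best_mse = net, mse

    encoder = MLP.__new__(MLP)
    k = len(enc_sizes) - 1
    encoder.W = best_net.W[:k]
    encoder.b = best_net.b[:k]
    encoder.activations = acts[:k]
    return EncoderTransform(encoder, lo, span), best_mse


class AutoencoderCox(_RiskEstimator):
    """Autoencoder bottleneck codes fed to a plain Cox model: risk = Z beta."""

    def __init__(self, encoder_depth=1, bottleneck=8, epochs=300,
                 batch_size=128, lr=3e-3, n_restarts=2, random_state=0):
        self.encoder_depth = encoder_depth
        self.bottleneck = bottleneck
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.n_restarts = n_restarts
        self.random_state = random_state

    def _fit(self, X, times, events):
        self.encoder_, self.reconstruction_mse_ = fit_autoencoder(
            X,
            encoder_depth=self.encoder_depth,
            bottleneck=self.bottleneck,
            seed=self.random_state,
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr=self.lr,
            n_restarts=self.n_restarts,
        )
        Z = self.encoder_.transform(X)
        # bottleneck codes can be collinear/degenerate: a small ridge and a
        # relaxed tolerance keep the downstream Cox fit well-posed without
        # changing the ranking materially
        beta, _, _, _ = newton_cox(Z, times, events, penalty=1e-4 * len(times),
                                   tol=1e-6, max_iter=200)
        self.coef_ = beta

    def _risk(self, X):
        return self.encoder_.transform(X) @ self.coef_


# --------------------------------------------------------------------------
# spec/kind layer


@dataclass(frozen=True)
class LearnerSpec:
    """A learner kind plus its hyperparameters (Table-style grid entry)."""

    kind: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown learner kind {self.kind!r}; expected one of {KINDS}")

    def label(self) -> str:
        hp = ",".join(f"{k}={v}" for k, v in sorted(self.hyperparameters.items(), key=lambda kv: kv[0]))
        return f"{self.kind}({hp})"


@dataclass
class FittedLearner:
    """An opaque trained base model with its spec and training covariates."""

    spec: LearnerSpec
    estimator: BaseEstimator
    covariate_names: tuple[str, ...]

    def predict(self, covariates) -> np.ndarray:
        return predict_risk(self, covariates)


def _build_estimator(spec: LearnerSpec, seed: int, validation_fraction: float) -> BaseEstimator:
    hp = dict(spec.hyperparameters)
    if spec.kind == "cox":
        return CoxPHLearner(**hp)
    if spec.kind == "pretrained_linear":
        return PretrainedLinearRisk(coef=hp.pop("coef"), covariate_names=hp.pop("covariate_names", None))
    if spec.kind == "coxnet":
        return CoxnetLearner(alpha=hp.pop("alpha", 0.5), lam=hp.pop("lam", 0.1))
    if spec.kind == "gb_cox":
        hp.setdefault("random_state", seed)
        return GradientBoostedCox(**hp)
    if spec.kind == "rsf":
        hp.setdefault("random_state", seed)
        return RandomSurvivalForestLearner(**hp)
    if spec.kind == "deepsurv":
        hp.setdefault("random_state", seed)
        hp.setdefault("validation_fraction", validation_fraction)
        return DeepSurvLearner(**hp)
    if spec.kind == "ae_cox":
        hp.setdefault("random_state", seed)
        return AutoencoderCox(**hp)
    raise ValueError(f"unknown learner kind {spec.kind!r}")


def fit_learner(
    spec: LearnerSpec,
    ds: SurvivalDataset,
    feature_set: FeatureSet | None = None,
    seed: int = 0,
    validation_fraction: float = 0.1,
) -> FittedLearner:
    """Fit one base learner on (complete) covariates of a feature set."""
    names = tuple(feature_set.covariate_names) if feature_set is not None else tuple(ds.covariate_names)
    X = ds.matrix(feature_set)
    if spec.kind == "pretrained_linear":
        hp = spec.hyperparameters
        coef_names = hp.get("covariate_names")
        if coef_names is not None:
            missing = [c for c in coef_names if c not in names]
            if missing:
                raise ValueError(f"pretrained coefficients name covariates outside the feature set: {missing}")
            idx = [names.index(c) for c in coef_names]
            X = X[:, idx]
            names = tuple(coef_names)
    est = _build_estimator(spec, seed, validation_fraction)
    est.fit(X, survival_y(ds.times, ds.events))
    return FittedLearner(spec=spec, estimator=est, covariate_names=names)


def predict_risk(m: FittedLearner, covariates) -> np.ndarray:
    """Score a complete covariate matrix with a fitted learner."""
    X = _check_matrix(covariates, len(m.covariate_names))
    return m.estimator.predict(X)


def _spec_complexity(spec: LearnerSpec):
    vals = []
    for k in sorted(spec.hyperparameters):
        v = spec.hyperparameters[k]
        vals.append(float(v) if isinstance(v, (int, float, bool)) else float(len(str(v))))
    return (len(vals), tuple(vals))


def grid_search(
    specs: Sequence[LearnerSpec],
    ds: SurvivalDataset,
    feature_set: FeatureSet | None = None,
    V: int = 5,
    seed: int = 0,
) -> LearnerSpec:
    """Pick the spec with the best mean out-of-fold Harrell C over V folds.

    Exact-score ties break toward the simpler spec (fewer hyperparameters,
    then smaller values).
    """
    specs = list(specs)
    if not specs:
        raise ValueError("empty hyperparameter grid")
    kinds = {s.kind for s in specs}
    if len(kinds) > 1:
        raise ValueError(f"grid mixes learner kinds: {sorted(kinds)}")
    if len(specs) == 1:
        return specs[0]
    kf = KFold(n_splits=V, shuffle=True, random_state=seed)
    scores = []
    for spec in specs:
        cs = []
        for fold, (tr, va) in enumerate(kf.split(np.arange(ds.n_patients))):
            m = fit_learner(spec, ds.subset(tr), feature_set, seed=seed + fold)
            r = m.predict(ds.subset(va).matrix(feature_set) if feature_set else ds.subset(va).covariates)
            cs.append(harrell_cindex(r, ds.times[va], ds.events[va]))
        scores.append(float(np.mean(cs)))
    best = max(range(len(specs)), key=lambda i: (scores[i],))
    tied = [i for i in range(len(specs)) if scores[i] == scores[best]]
    return specs[min(tied, key=lambda i: _spec_complexity(specs[i]))]


def default_library(
    pretrained_coef=None,
    pretrained_names=None,
    rsf_trees: int = 500,
    deepsurv_neurons: int = 90,
) -> list[LearnerSpec]:
    """The default stacking library.

    One linear prognostic-score entry (a pretrained score if coefficients are
    given, otherwise a plain Cox model), a random survival forest, five
    elastic-net Cox models over the mixing grid {0, .25, .5, .75, 1}, six
    gradient-boosting configurations (N in {100, 500, 1000} x depth {1, 2}),
    two single-hidden-layer deepsurv nets (tanh and selu) and four
    autoencoder-Cox configurations (depth {1, 3} x bottleneck {8, 14}).
    """
    lib: list[LearnerSpec] = []
    if pretrained_coef is not None:
        lib.append(LearnerSpec("pretrained_linear", {
            "coef": tuple(np.asarray(pretrained_coef, dtype=float)),
            "covariate_names": None if pretrained_names is None else tuple(pretrained_names),
        }))
    else:
        lib.append(LearnerSpec("cox", {}))
    lib.append(LearnerSpec("rsf", {"n_trees": rsf_trees}))
    for a in (0.0, 0.25, 0.5, 0.75, 1.0):
        lib.append(LearnerSpec("coxnet", {"alpha": a, "lam": 0.01}))
    for n in (100, 500, 1000):
        for depth in (1, 2):
            lib.append(LearnerSpec("gb_cox", {"n_estimators": n, "max_depth": depth}))
    for act in ("tanh", "selu"):
        lib.append(LearnerSpec("deepsurv", {"activation": act, "n_neurons": deepsurv_neurons}))
    for depth in (1, 3):
        for p in (8, 14):
            lib.append(LearnerSpec("ae_cox", {"encoder_depth": depth, "bottleneck": p}))
    return lib
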
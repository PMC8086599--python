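"""Concordance metrics and bootstrap inference for survival risk scores.

Harrell's C-index is the fraction of comparable patient pairs whose risk
ordering matches their survival ordering.  An ordered pair (i, j) is
comparable when ``T_i < T_j`` and patient i had the event, or when
``T_i == T_j`` with i an event and j censored (the event goes first).
Tied event times between two events are not comparable; tied risks count 0.5.

Uno's C-index reweights comparable event pairs by the inverse squared
Kaplan-Meier estimate of the censoring survival function, G(t), evaluated
left-continuously at the earlier event time, which removes the dependence of
the statistic on the study's own censoring distribution (IPCW).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CIndexResult",
    "ComparisonResult",
    "harrell_cindex",
    "uno_cindex",
    "bootstrap_ci",
    "compare_models",
    "evaluate_stratified",
]

_CHUNK = 512  # rows of the pair matrix processed at a time


def _check_inputs(risk, times, events):
    risk = np.asarray(risk, dtype=float).ravel()
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events).astype(int).ravel()
    if not (len(risk) == len(times) == len(events)):
        raise ValueError("risk, times and events must have equal length")
    if np.any(~np.isfinite(risk)):
        raise ValueError("risk scores must be finite")
    return risk, times, events


def _pair_masses(risk, times, events, weights=None):
    """Accumulate (concordance mass, comparable mass) over ordered pairs.

    ``weights`` is an optional per-pair weight taken from the earlier (event)
    member i; None means unit weights (Harrell).  Uno restricts comparability
    to strict ``T_i < T_j`` by passing weight 0 where not applicable; here the
    tie clause (event before censoring at equal times) applies only when
    ``weights is None``.
    """
    num = 0.0
    den = 0.0
    ev_idx = np.flatnonzero(events == 1)
    for start in range(0, len(ev_idx), _CHUNK):
        i = ev_idx[start : start + _CHUNK]
        ti = times[i][:, None]
        comparable = times[None, :] > ti
        if weights is None:
            comparable = comparable | ((times[None, :] == ti) & (events[None, :] == 0))
        comparable[np.arange(len(i)), i] = False  # exclude the diagonal
        ri = risk[i][:, None]
        conc = (ri > risk[None, :]) + 0.5 * (ri == risk[None, :])
        w = 1.0 if weights is None else weights[i][:, None]
        num += float(np.sum(w * conc * comparable))
        den += float(np.sum(w * comparable))
    return num, den


def harrell_cindex(risk, times, events) -> float:
    """Harrell's concordance index of a risk score against right-censored outcomes.

    Higher risk must pair with shorter survival: 1 is perfect concordance,
    0.5 chance level, 0 perfect discordance.  Raises if no pair is comparable
    (e.g. everything censored).
    """
    risk, times, events = _check_inputs(risk, times, events)
    num, den = _pair_masses(risk, times, events)
    if den == 0.0:
        raise ValueError("no comparable pairs: concordance undefined")
    return num / den


def censoring_km(times, events):
    """Kaplan-Meier estimate of the censoring survival function G(t).

    Roles are swapped: censorings are the 'events' of this curve.  Returns
    ``(grid, surv)`` with ``surv[k] = G(grid[k])`` right-continuous; use
    :func:`km_left` for the left-continuous evaluation G(t-).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    order = np.argsort(times, kind="stable")
    t = times[order]
    cens = 1 - events[order]
    grid, first, inverse = np.unique(t, return_index=True, return_inverse=True)
    n = len(t)
    at_risk = n - first
    d = np.bincount(inverse, weights=cens.astype(float), minlength=len(grid))
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = 1.0 - d / at_risk
    surv = np.cumprod(factors)
    return grid, surv


def km_left(grid, surv, t):
    """Left-continuous step-function evaluation: S(t-) of a KM curve."""
    idx = np.searchsorted(grid, np.asarray(t, dtype=float), side="left") - 1
    out = np.ones(np.shape(t), dtype=float)
    pos = idx >= 0
    out[pos] = surv[idx[pos]]
    return out


def uno_cindex(risk, times, events, tau: float | None = None) -> float:
    """Uno's IPCW concordance index.

    Comparable pairs are event pairs with strictly ordered times,
    ``T_i < T_j`` and ``T_i < tau``, weighted by ``G(T_i-)**-2`` where G is
    the Kaplan-Meier censoring-survival curve.  Pairs whose weight would
    divide by ``G = 0`` are dropped; with no censoring Uno's C equals
    Harrell's exactly.  ``tau`` defaults to the largest follow-up time at
    which G is still positive.
    """
    risk, times, events = _check_inputs(risk, times, events)
    grid, surv = censoring_km(times, events)
    if tau is None:
        positive = surv > 0.0
        tau = float(grid[positive][-1]) + np.finfo(float).eps if positive.any() else float(grid[-1])
        tau = np.nextafter(tau, np.inf)
    g_left = km_left(grid, surv, times)
    with np.errstate(divide="ignore"):
        w = np.where(g_left > 0.0, g_left**-2.0, 0.0)
    w = np.where((events == 1) & (times < tau), w, 0.0)
    num, den = _pair_masses(risk, times, events, weights=w)
    if den == 0.0:
        raise ValueError("no comparable weighted pairs: Uno's C undefined")
    return num / den


@dataclass(frozen=True)
class CIndexResult:
    """A concordance estimate with a percentile-bootstrap confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    metric: str
    n_redrawn: int = 0


@dataclass(frozen=True)
class ComparisonResult:
    """Two-model concordance comparison under H0: C1 - C2 = 0."""

    delta: float
    ci_overlap_significant: bool
    bootstrap_p: float


def _metric_fn(metric: str):
    if metric == "harrell":
        return harrell_cindex
    if metric == "uno":
        return uno_cindex
    raise ValueError(f"unknown metric {metric!r} (expected 'harrell' or 'uno')")


def bootstrap_ci(
    risk,
    times,
    events,
    metric: str = "harrell",
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> CIndexResult:
    """Patient-level percentile bootstrap for a concordance metric.

    Resamples patients with replacement B times; resamples on which the
    metric is undefined (no comparable pairs) are redrawn and counted.
    Deterministic given the seed.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    risk, times, events = _check_inputs(risk, times, events)
    fn = _metric_fn(metric)
    estimate = fn(risk, times, events)  # raises if undefined on the original sample
    rng = np.random.default_rng(seed)
    n = len(risk)
    reps = np.empty(B)
    redrawn = 0
    for b in range(B):
        for _ in range(1000):
            idx = rng.integers(0, n, size=n)
            try:
                reps[b] = fn(risk[idx], times[idx], events[idx])
                break
            except ValueError:
                redrawn += 1
        else:
            raise RuntimeError("could not draw a bootstrap resample with comparable pairs")
    alpha = 1.0 - level
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return CIndexResult(float(estimate), float(lo), float(hi), B, metric, redrawn)


def compare_models(
    risk_a,
    risk_b,
    times,
    events,
    B: int = 1000,
    seed: int = 0,
    metric: str = "harrell",
    level: float = 0.95,
) -> ComparisonResult:
    """Paired-bootstrap comparison of two risk scores on the same patients.

    ``ci_overlap_significant`` applies the conservative rule of declaring a
    difference when the two marginal bootstrap CIs are disjoint;
    ``bootstrap_p`` is the two-sided p-value from the paired resampled
    distribution of the concordance difference (same resample indices for
    both models).
    """
    risk_a, times, events = _check_inputs(risk_a, times, events)
    risk_b, _, _ = _check_inputs(risk_b, times, events)
    if len(risk_a) != len(risk_b):
        raise ValueError("risk vectors must have equal length")
    fn = _metric_fn(metric)
    delta = fn(risk_a, times, events) - fn(risk_b, times, events)
    rng = np.random.default_rng(seed)
    n = len(risk_a)
    ca = np.empty(B)
    cb = np.empty(B)
    b = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        try:
            ca[b] = fn(risk_a[idx], times[idx], events[idx])
            cb[b] = fn(risk_b[idx], times[idx], events[idx])
        except ValueError:
            continue
        b += 1
    alpha = 1.0 - level
    qa = np.percentile(ca, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    qb = np.percentile(cb, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    disjoint = qa[0] > qb[1] or qb[0] > qa[1]
    d = ca - cb
    p = 2.0 * min(np.mean(d <= 0.0), np.mean(d >= 0.0))
    return ComparisonResult(float(delta), bool(disjoint), float(min(p, 1.0)))


def evaluate_stratified(
    risk,
    times,
    events,
    group_labels,
    metric: str = "harrell",
    B: int = 1000,
    seed: int = 0,
) -> dict[str, CIndexResult]:
    """Per-group concordance (plus the pooled value under key ``"pooled"``).

    Groups on which the metric is undefined are skipped with a warning.
    """
    risk, times, events = _check_inputs(risk, times, events)
    groups = np.asarray(group_labels)
    out: dict[str, CIndexResult] = {}
    out["pooled"] = bootstrap_ci(risk, times, events, metric=metric, B=B, seed=seed)
    for g in np.unique(groups):
        m = groups == g
        try:
            out[str(g)] = bootstrap_ci(
                risk[m], times[m], events[m], metric=metric, B=B, seed=seed
            )
        except (ValueError, RuntimeError) as err:
            warnings.warn(f"group {g!r} skipped: {err}")
    return out
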
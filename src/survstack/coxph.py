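"""Cox partial likelihood (Breslow/Efron ties) and a Newton-Raphson fitter.

The proportional-hazards model factorises the hazard as
``h(t | X) = h0(t) * exp(r(X))`` with a linear relative log-risk
``r(X) = beta @ X``.  Fitting maximises the log partial likelihood

    log PL(beta) = sum_i delta_i * [ r_i - log sum_{l in R(T_i)} exp(r_l) ],

where the risk set ``R(T_i)`` holds every patient still under observation at
``T_i``.  Tied event times use the Breslow convention by default (the full
risk set for every tied event); Efron's correction is available as an option.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

__all__ = ["cox_partial_likelihood", "newton_cox", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    """Raised when the Newton iterations fail to reach the gradient tolerance."""

    def __init__(self, message: str, n_iter: int, grad_norm: float):
        super().__init__(f"{message} (iterations={n_iter}, grad_norm={grad_norm:.3e})")
        self.n_iter = n_iter
        self.grad_norm = grad_norm


def _event_groups(times, events):
    """Sorted time order plus, per distinct event time, the tied-event slices."""
    order = np.argsort(times, kind="stable")
    t = times[order]
    e = events[order]
    return order, t, e


def cox_partial_likelihood(risk, times, events, ties: str = "breslow") -> float:
    """Log partial likelihood of a fixed per-patient log-risk vector.

    Adding a constant to every risk leaves the value unchanged, and a dataset
    with no observed events contributes an empty sum (value 0).
    """
    risk = np.asarray(risk, dtype=float).ravel()
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events).astype(int).ravel()
    if not (len(risk) == len(times) == len(events)):
        raise ValueError("risk, times and events must have equal length")
    if np.any(np.isnan(risk)):
        raise ValueError("risk contains NaN")
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie convention {ties!r}")
    if events.sum() == 0:
        return 0.0

    order, t, e = _event_groups(times, events)
    r = risk[order]
    # log of the risk-set sum, computed right-to-left; risk set = {l : T_l >= T_i}
    n = len(r)
    log_cum = np.logaddexp.accumulate(r[::-1])[::-1]
    # first index of each tied-time block
    first_of_block = np.zeros(n, dtype=int)
    for i in range(1, n):
        first_of_block[i] = first_of_block[i - 1] if t[i] == t[i - 1] else i

    ll = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        ev = np.flatnonzero(e[i:j] == 1) + i
        d = len(ev)
        if d:
            log_s0 = log_cum[first_of_block[i]]
            ll += float(r[ev].sum())
            if ties == "breslow" or d == 1:
                ll -= d * log_s0
            else:  # Efron: progressively remove the tied events' average mass
                log_tied = logsumexp(r[ev])
                for m in range(d):
                    if m == 0:
                        ll -= log_s0
                    else:
                        # log(S0 - (m/d) * sum_tied)
                        frac = m / d
                        a, b = log_s0, np.log(frac) + log_tied
                        ll -= a + np.log1p(-np.exp(b - a))
        i = j
    return float(ll)


def _cox_ll_grad_hess(X, times, events, beta, ties, penalty=0.0):
    """Ridge-penalised log PL with analytic gradient and Hessian.

    Objective: log PL(beta) - penalty/2 * ||beta||^2 (maximised).
    Breslow and Efron tie handling both supported.
    """
    n, p = X.shape
    order = np.argsort(times, kind="stable")
    Xs = X[order]
    t = times[order]
    e = events[order]
    eta = Xs @ beta
    # numeric stabilisation: shift by max (cancels in all ratios)
    shift = eta.max() if n else 0.0
    w = np.exp(eta - shift)
    wx = w[:, None] * Xs
    wxx = np.einsum("i,ij,ik->ijk", w, Xs, Xs)
    # suffix sums over the risk set
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        ev = np.flatnonzero(e[i:j] == 1) + i
        d = len(ev)
        if d:
            s0, s1, s2 = S0[i], S1[i], S2[i]
            ll += float(eta[ev].sum() - d * shift)
            if ties == "breslow" or d == 1:
                mu = s1 / s0
                ll -= d * np.log(s0)
                grad += Xs[ev].sum(axis=0) - d * mu
                hess -= d * (s2 / s0 - np.outer(mu, mu))
            else:
                tied_w = w[ev].sum()
                tied_wx = wx[ev].sum(axis=0)
                tied_wxx = wxx[ev].sum(axis=0)
                grad += Xs[ev].sum(axis=0)
                for m in range(d):
                    frac = m / d
                    a0 = s0 - frac * tied_w
                    a1 = s1 - frac * tied_wx
                    a2 = s2 - frac * tied_wxx
                    mu = a1 / a0
                    ll -= np.log(a0)
                    grad -= mu
                    hess -= a2 / a0 - np.outer(mu, mu)
        i = j
    if penalty:
        ll -= 0.5 * penalty * float(beta @ beta)
        grad -= penalty * beta
        hess -= penalty * np.eye(p)
    return ll, grad, hess


def newton_cox(
    X,
    times,
    events,
    ties: str = "breslow",
    penalty: float = 0.0,
    tol: float = 1e-8,
    max_iter: int = 100,
):
    """Maximise the (optionally ridge-penalised) Cox partial likelihood.

    Newton-Raphson with step halving, started at beta = 0; converges when the
    per-observation gradient max-norm drops below ``tol`` (i.e. the summed
    score is below ``tol * n``).  Returns
    ``(beta, standard_errors, loglik, n_iter)``; standard errors come from the
    inverse observed information.
    """
    X = np.asarray(X, dtype=float)
    times = np.asarray(times, dtype=float).ravel()
    events = np.asarray(events).astype(int).ravel()
    n, p = X.shape
    beta = np.zeros(p)
    ll, grad, hess = _cox_ll_grad_hess(X, times, events, beta, ties, penalty)
    gtol = tol * max(n, 1)
    for it in range(1, max_iter + 1):
        gnorm = float(np.abs(grad).max()) if p else 0.0
        if gnorm < gtol:
            cov = np.linalg.inv(-hess) if p else np.zeros((0, 0))
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            return beta, se, ll, it - 1
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        # step halving keeps the objective non-decreasing
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new, grad_new, hess_new = _cox_ll_grad_hess(
                X, times, events, cand, ties, penalty
            )
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise ConvergenceError("step halving failed", it, gnorm)
        stalled = ll_new - ll < 1e-12 * (abs(ll) + 1.0)
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        # objective at float precision with a statistically negligible score:
        # further iterations cannot improve, so accept
        if stalled and float(np.abs(grad).max()) < 1e-6 * max(n, 1):
            break
    gnorm = float(np.abs(grad).max())
    if gnorm < gtol or gnorm < 1e-6 * max(n, 1):
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        return beta, se, ll, it
    raise ConvergenceError("Newton iterations did not converge", max_iter, gnorm)
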
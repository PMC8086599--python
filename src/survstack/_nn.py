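"""Minimal dense feed-forward networks with manual backprop and Adam.

Just enough machinery for the two neural survival components: a risk network
trained on the Cox partial likelihood and a reconstruction autoencoder.
Activations: tanh, selu, relu, sigmoid, linear.
"""

from __future__ import annotations

import numpy as np

_SELU_SCALE = 1.0507009873554805
_SELU_ALPHA = 1.6732632423543772


def _act(name, z):
    if name == "linear":
        return z
    if name == "tanh":
        return np.tanh(z)
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "selu":
        return _SELU_SCALE * np.where(z > 0, z, _SELU_ALPHA * np.expm1(z))
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    raise ValueError(f"unknown activation {name!r}")


def _act_grad(name, z, a):
    """d activation / d z, reusing the forward value ``a`` where cheap."""
    if name == "linear":
        return np.ones_like(z)
    if name == "tanh":
        return 1.0 - a * a
    if name == "relu":
        return (z > 0).astype(z.dtype)
    if name == "selu":
        return _SELU_SCALE * np.where(z > 0, 1.0, _SELU_ALPHA * np.exp(z))
    if name == "sigmoid":
        return a * (1.0 - a)
    raise ValueError(f"unknown activation {name!r}")


class MLP:
    """Fully-connected network; ``activations[k]`` follows layer k."""

    def __init__(self, sizes, activations, rng):
        assert len(activations) == len(sizes) - 1
        self.activations = list(activations)
        self.W = []
        self.b = []
        for fan_in, fan_out, act in zip(sizes, sizes[1:], activations):
            if act in ("relu", "selu"):
                scale = np.sqrt(2.0 / fan_in)
            else:
                scale = np.sqrt(1.0 / fan_in)
            self.W.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            # slightly positive bias keeps relu units alive at initialisation
            self.b.append(np.full(fan_out, 0.05) if act == "relu" else np.zeros(fan_out))

    def forward(self, X):
        """Return (pre-activations, activations); activations[-1] is the output."""
        zs, acts = [], [X]
        a = X
        for W, b, name in zip(self.W, self.b, self.activations):
            z = a @ W + b
            a = _act(name, z)
            zs.append(z)
            acts.append(a)
        return zs, acts

    def predict(self, X):
        return self.forward(X)[1][-1]

    def backward(self, zs, acts, grad_out):
        """Gradients of a scalar loss given d loss / d output."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = grad_out
        for k in range(len(self.W) - 1, -1, -1):
            delta = delta * _act_grad(self.activations[k], zs[k], acts[k + 1])
            gW[k] = acts[k].T @ delta
            gb[k] = delta.sum(axis=0)
            if k:
                delta = delta @ self.W[k].T
        return gW, gb

    def get_weights(self):
        return [w.copy() for w in self.W], [b.copy() for b in self.b]

    def set_weights(self, weights):
        W, b = weights
        self.W = [w.copy() for w in W]
        self.b = [x.copy() for x in b]


class Adam:
    """Adaptive-moment gradient descent over a flat list of parameter arrays."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        corr1 = 1.0 - self.b1**self.t
        corr2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


def cox_risk_gradient(risk, times, events):
    """d(-log PL)/d risk for a (mini)batch, Breslow ties.

    With patients sorted by time inside the batch, the risk-set sums reduce to
    suffix cumulative sums; the gradient for patient i is
    ``-(delta_i - exp(r_i) * sum_{events d: T_d <= T_i} d_d / S0(T_d))``.
    """
    risk = np.asarray(risk, dtype=float).ravel()
    order = np.argsort(times, kind="stable")
    r = risk[order]
    t = np.asarray(times)[order]
    e = np.asarray(events).astype(int)[order]
    n = len(r)
    shift = r.max() if n else 0.0
    w = np.exp(r - shift)
    S0 = np.cumsum(w[::-1])[::-1]
    # share the risk-set sum across tied times (Breslow)
    first = np.zeros(n, dtype=int)
    for i in range(1, n):
        first[i] = first[i - 1] if t[i] == t[i - 1] else i
    S0 = S0[first]
    # cumulative number of events per unit of S0 up to each time
    inc = np.where(e == 1, 1.0 / S0, 0.0)
    cum = np.cumsum(inc)
    # all tied patients share the cumulative sum through the end of their block
    last = np.zeros(n, dtype=int)
    last[-1] = n - 1
    for i in range(n - 2, -1, -1):
        last[i] = last[i + 1] if t[i] == t[i + 1] else i
    cum = cum[last]
    grad_sorted = -(e - w * cum)
    grad = np.empty(n)
    grad[order] = grad_sorted
    return grad


def neg_log_pl(risk, times, events):
    """-log PL, Breslow; convenience wrapper for validation monitoring."""
    from .coxph import cox_partial_likelihood

    return -cox_partial_likelihood(risk, times, events)
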
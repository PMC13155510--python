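"""Minimal dense tanh network with hand-written backpropagation and Adam.

Used by the physics-informed trainer in :mod:`gliomarl.surrogate`; kept
deliberately small (two inputs, one output, a few hidden layers) so that
training stays cheap on a single CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "Adam"]


class MLP:
    """Fully connected tanh network f: R^d_in -> R^d_out."""

    def __init__(self, sizes, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.sizes = list(sizes)
        self.W, self.b = [], []
        for n_in, n_out in zip(sizes[:-1], sizes[1:]):
            # Xavier/Glorot initialisation for tanh layers
            s = np.sqrt(6.0 / (n_in + n_out))
            self.W.append(rng.uniform(-s, s, size=(n_in, n_out)))
            self.b.append(np.zeros(n_out))

    # -- parameter plumbing -------------------------------------------------
    def params(self):
        return self.W + self.b

    def set_params(self, flat):
        k = len(self.W)
        self.W = [np.asarray(p) for p in flat[:k]]
        self.b = [np.asarray(p) for p in flat[k:]]

    def copy(self) -> "MLP":
        m = MLP.__new__(MLP)
        m.sizes = list(self.sizes)
        m.W = [w.copy() for w in self.W]
        m.b = [b.copy() for b in self.b]
        return m

    # -- forward / backward -------------------------------------------------
    def forward(self, x, cache: bool = False):
        """x: (n, d_in).  Hidden layers tanh, final layer linear."""
        h = np.asarray(x, dtype=float)
        caches = [h]
        n_layers = len(self.W)
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            h = z if i == n_layers - 1 else np.tanh(z)
            caches.append(h)
        return (h, caches) if cache else h

    def __call__(self, x):
        return self.forward(x)

    def backward(self, caches, dLdy):
        """Gradients of sum(dLdy * y) w.r.t. parameters; dLdy: (n, d_out)."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = np.asarray(dLdy, dtype=float)
        for i in range(len(self.W) - 1, -1, -1):
            h_in = caches[i]
            gW[i] = h_in.T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * (1.0 - caches[i] ** 2)
        return gW + gb


class Adam:
    """Adam over an arbitrary list of parameter arrays."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            out.append(p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out
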
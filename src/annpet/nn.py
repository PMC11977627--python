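"""Minimal seeded neural-network engine (numpy) for the event positioner.

A small residual multilayer perceptron: an input projection, ``n_blocks``
residual blocks (two linear layers with a ReLU and an identity skip), and a
linear head.  Trained with Adam on mean-squared error.  Everything is driven
by one ``numpy.random.Generator``, so training is bit-reproducible at fixed
seed, data and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NetConfig", "ResidualMLP"]


@dataclass(frozen=True)
class NetConfig:
    hidden: int = 96
    n_blocks: int = 3           # 2 layers each; depth = 2 + 2*n_blocks
    epochs: int = 12
    batch_size: int = 512
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8


class ResidualMLP:
    """Residual MLP regressor with Adam/MSE training."""

    def __init__(self, n_in: int, n_out: int, cfg: NetConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.n_in = n_in
        self.n_out = n_out
        h = cfg.hidden
        self.params: list[np.ndarray] = []

        def lin(n1, n2):
            w = rng.normal(0.0, np.sqrt(2.0 / n1), (n1, n2))
            b = np.zeros(n2)
            self.params += [w, b]

        lin(n_in, h)
        for _ in range(cfg.n_blocks):
            lin(h, h)
            lin(h, h)
        lin(h, n_out)
        self._m = [np.zeros_like(p) for p in self.params]
        self._v = [np.zeros_like(p) for p in self.params]
        self._step = 0

    # -- forward / backward ---------------------------------------------
    def _forward(self, x, keep=False):
        cfg = self.cfg
        P = self.params
        cache = []
        a = x @ P[0] + P[1]
        pre0 = a
        a = np.maximum(a, 0.0)
        cache.append((x, pre0))
        k = 2
        for _ in range(cfg.n_blocks):
            z1 = a @ P[k] + P[k + 1]
            h1 = np.maximum(z1, 0.0)
            z2 = h1 @ P[k + 2] + P[k + 3]
            out = a + z2            # identity skip
            post = np.maximum(out, 0.0)
            cache.append((a, z1, h1, out))
            a = post
            k += 4
        y = a @ P[k] + P[k + 1]
        cache.append(a)
        return (y, cache) if keep else y

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(x, float))

    def _backward(self, x, y_true):
        P = self.params
        y, cache = self._forward(x, keep=True)
        n = x.shape[0]
        grads = [np.zeros_like(p) for p in P]
        dy = 2.0 * (y - y_true) / n / y.shape[1]
        loss = float(np.mean((y - y_true) ** 2))
        a_last = cache[-1]
        k = len(P) - 2
        grads[k] = a_last.T @ dy
        grads[k + 1] = dy.sum(axis=0)
        da = dy @ P[k].T
        for bi in range(self.cfg.n_blocks - 1, -1, -1):
            a_in, z1, h1, out = cache[1 + bi]
            da = da * (out > 0)     # through the post-block ReLU
            kk = 2 + 4 * bi
            dz2 = da
            grads[kk + 2] = h1.T @ dz2
            grads[kk + 3] = dz2.sum(axis=0)
            dh1 = dz2 @ P[kk + 2].T
            dz1 = dh1 * (z1 > 0)
            grads[kk] = a_in.T @ dz1
            grads[kk + 1] = dz1.sum(axis=0)
            da = dz1 @ P[kk].T + da  # skip path
        x_in, pre0 = cache[0]
        da = da * (pre0 > 0)
        grads[0] = x_in.T @ da
        grads[1] = da.sum(axis=0)
        return loss, grads

    def _adam(self, grads):
        cfg = self.cfg
        self._step += 1
        b1, b2 = cfg.adam_beta1, cfg.adam_beta2
        lr = cfg.learning_rate * np.sqrt(1 - b2**self._step) / (1 - b1**self._step)
        for p, g, m, v in zip(self.params, grads, self._m, self._v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr * m / (np.sqrt(v) + cfg.adam_eps)

    def fit(self, x, y, rng: np.random.Generator, verbose: bool = False):
        """Train; returns the per-epoch mean training loss history."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        n = x.shape[0]
        if n == 0:
            raise ValueError("empty training set")
        cfg = self.cfg
        history = []
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for lo in range(0, n, cfg.batch_size):
                sel = order[lo:lo + cfg.batch_size]
                loss, grads = self._backward(x[sel], y[sel])
                self._adam(grads)
                losses.append(loss * sel.size)
            history.append(float(np.sum(losses) / n))
            if verbose:
                print(f"epoch {epoch + 1}/{cfg.epochs}  mse={history[-1]:.5f}")
        return history

    # -- persistence -----------------------------------------------------
    def state_dict(self) -> dict:
        return {f"p{i}": p for i, p in enumerate(self.params)}

    def load_state_dict(self, d: dict) -> None:
        for i in range(len(self.params)):
            self.params[i][...] = d[f"p{i}"]
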
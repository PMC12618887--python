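"""Dense networks and the Adam optimizer used by the VAE recognition and
generative models.

All networks are multilayer perceptrons with softplus activations on hidden
layers, the activation family used throughout the model architecture.
Distribution heads emit a location and a raw scale; scales are mapped through
``softplus(raw) + 1e-6`` to keep them strictly positive with stable gradients.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat

SCALE_FLOOR = 1e-6

__all__ = ["MLP", "LocScaleHead", "Adam", "init_linear", "SCALE_FLOOR"]


def init_linear(rng: np.random.Generator, n_in: int, n_out: int, scale: float | None = None):
    """Fan-in scaled Gaussian initialization."""
    if scale is None:
        scale = 1.0 / np.sqrt(n_in)
    W = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
    b = Tensor(np.zeros(n_out), requires_grad=True)
    return W, b


class MLP:
    """Softplus MLP: hidden layers activated, final layer linear by default."""

    def __init__(self, rng, sizes, final_activation: bool = False):
        self.sizes = list(sizes)
        self.final_activation = final_activation
        self.layers = [
            init_linear(rng, a, b) for a, b in zip(sizes[:-1], sizes[1:])
        ]

    @property
    def params(self):
        return [p for layer in self.layers for p in layer]

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        last = len(self.layers) - 1
        for i, (W, b) in enumerate(self.layers):
            h = h @ W + b
            if i < last or self.final_activation:
                h = h.softplus()
        return h


class LocScaleHead:
    """Two linear heads on a shared input: location and positive scale."""

    def __init__(self, rng, n_in: int, n_out: int):
        self.loc = init_linear(rng, n_in, n_out)
        # raw-scale bias starts at softplus^{-1}(1) so initial scales are ~1
        self.raw_scale = init_linear(rng, n_in, n_out)
        self.raw_scale[1].data[:] = np.log(np.e - 1.0)

    @property
    def params(self):
        return list(self.loc) + list(self.raw_scale)

    def __call__(self, h: Tensor):
        loc = h @ self.loc[0] + self.loc[1]
        scale = (h @ self.raw_scale[0] + self.raw_scale[1]).softplus() + SCALE_FLOOR
        return loc, scale


class Adam:
    """Adam with global-norm gradient clipping and update skipping.

    The skip rule discards a minibatch update outright when the gradient norm
    exceeds ``skip_factor`` times a running high quantile of recent norms, so
    that at converged thresholds it fires on a vanishing fraction of steps.
    """

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 clip_factor=20.0, skip_factor=50.0, warmup=50):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0
        self.clip_factor = clip_factor
        self.skip_factor = skip_factor
        self.warmup = warmup
        self._norms: list[float] = []
        self.n_clipped = 0
        self.n_skipped = 0

    def _grad_norm(self):
        total = 0.0
        for p in self.params:
            if p.grad is not None:
                g = p.grad.ravel()
                total += float(g @ g)
        return np.sqrt(total)

    def step(self):
        norm = self._grad_norm()
        ref = np.median(self._norms[-500:]) if len(self._norms) >= self.warmup else None
        self._norms.append(norm)
        if ref is not None and norm > self.skip_factor * ref:
            self.n_skipped += 1
            self.zero_grad()
            return False
        scale = 1.0
        if ref is not None and norm > self.clip_factor * ref:
            scale = self.clip_factor * ref / norm
            self.n_clipped += 1
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        step_scale = self.lr * np.sqrt(b2t) / b1t
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if scale != 1.0:
                g = g * scale
            m, v = self.m[i], self.v[i]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * np.square(g)
            p.data -= step_scale * m / (np.sqrt(v) + self.eps * np.sqrt(b2t))
        self.zero_grad()
        return True

    def zero_grad(self):
        for p in self.params:
            p.grad = None
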
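"""Closed-form densities, KL divergences, entropies and reparameterized
samplers for the factorized Gaussian and Laplace families used by the models.

All functions operate on numpy arrays elementwise; reductions are left to
the caller.  The Laplace--Laplace KL is available in closed form, which is
what makes the fully Laplace latent pathway trainable without Monte Carlo
KL estimates.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "gaussian_logpdf",
    "laplace_logpdf",
    "gaussian_kl_std",
    "gaussian_kl",
    "laplace_kl",
    "gaussian_entropy",
    "laplace_entropy",
    "sample_gaussian",
    "sample_laplace",
    "laplace_noise",
]


def gaussian_logpdf(x, loc, scale):
    return -0.5 * np.log(2 * np.pi * scale**2) - (x - loc) ** 2 / (2 * scale**2)


def laplace_logpdf(x, loc, scale):
    return -np.log(2 * scale) - np.abs(x - loc) / scale


def gaussian_kl_std(mu, sigma):
    """KL( N(mu, sigma^2) || N(0, 1) ), elementwise."""
    return 0.5 * (mu**2 + sigma**2 - 1.0) - np.log(sigma)


def gaussian_kl(mu1, s1, mu2, s2):
    return np.log(s2 / s1) + (s1**2 + (mu1 - mu2) ** 2) / (2 * s2**2) - 0.5


def laplace_kl(mu1, b1, mu2, b2):
    """KL( La(mu1, b1) || La(mu2, b2) ), elementwise."""
    d = np.abs(mu1 - mu2)
    return np.log(b2 / b1) + (b1 * np.exp(-d / b1) + d) / b2 - 1.0


def gaussian_entropy(sigma):
    return 0.5 * np.log(2 * np.pi * np.e * sigma**2)


def laplace_entropy(b):
    return 1.0 + np.log(2.0 * b)


def sample_gaussian(rng, loc, scale, size=None):
    shape = np.broadcast_shapes(np.shape(loc), np.shape(scale))
    if size is not None:
        shape = tuple(np.atleast_1d(size)) + shape
    return loc + scale * rng.standard_normal(shape)


def laplace_noise(rng, shape, dtype=np.float64):
    """Standard Laplace noise via the inverse CDF of a uniform draw."""
    u = rng.random(size=shape, dtype=np.dtype(dtype)) - 0.5
    u = np.clip(u, -0.5 + 1e-7, 0.5 - 1e-7)
    return -np.sign(u) * np.log1p(-2.0 * np.abs(u))


def sample_laplace(rng, loc, scale, size=None):
    shape = np.broadcast_shapes(np.shape(loc), np.shape(scale))
    if size is not None:
        shape = tuple(np.atleast_1d(size)) + shape
    return loc + scale * laplace_noise(rng, shape)
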
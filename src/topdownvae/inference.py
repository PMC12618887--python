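"""Sampling-hypothesis response simulation and posterior validation.

Under the sampling hypothesis, instantaneous neural activity is a
stochastic sample from the posterior over latents; a spike count in a time
window corresponds to the mean of a small number of samples (one sample per
~20 ms in V1, with slower turnover at higher levels).  A
:class:`WindowScheme` states how many independent Z2 draws a window
contains and how many Z1 draws are averaged under each Z2 draw, so the
"50 ms" scheme is one Z2 draw with three Z1 draws, and a "400 ms" window
can be realized as 1x20, 2x10 or 4x5.

Feedback interventions replace the Z2 source: `prior_z2` draws Z2 from its
prior while the image still reaches Z1 through the feed-forward pathway
(an "early response" condition), `prior_both` draws both layers from the
generative prior ("pre-stimulus"), and `clamp_z2_zero` feeds a zero vector
into the top-down pathway.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import dists

__all__ = [
    "WindowScheme",
    "ResponseMatrix",
    "parse_scheme",
    "samples_per_window",
    "encode",
    "sample_responses",
    "marginal_z1_mean",
    "snis_weights",
    "snis_generative_posterior",
]

CONDITIONS = ("intact", "prior_z2", "prior_both", "clamp_z2_zero")


@dataclass(frozen=True)
class WindowScheme:
    """n_z2_draws independent Z2 samples, n_z1_per_z2 Z1 samples under each."""

    n_z2_draws: int = 1
    n_z1_per_z2: int = 3
    label: str = ""

    def __post_init__(self):
        if self.n_z2_draws < 1 or self.n_z1_per_z2 < 1:
            raise ValueError("sample counts must be >= 1")


def parse_scheme(label: str) -> WindowScheme:
    """Parse labels like '1x3', '2x10', '4x5' into a WindowScheme."""
    m = re.fullmatch(r"(\d+)\s*[x×]\s*(\d+)", label.strip())
    if not m:
        raise ValueError(f"cannot parse scheme label {label!r}")
    return WindowScheme(int(m.group(1)), int(m.group(2)), label=label)


def samples_per_window(window_ms: float, sample_interval_ms: float = 20.0) -> int:
    """Number of posterior samples available in a response window.

    With the V1 autocorrelation time of ~20 ms per sample, a 500 ms trial
    yields 25 samples.
    """
    if sample_interval_ms <= 0:
        raise ValueError("sample interval must be positive")
    return int(round(window_ms / sample_interval_ms))


@dataclass
class ResponseMatrix:
    """units x trials (x stimuli) sampled responses with provenance."""

    values: np.ndarray
    scheme: WindowScheme
    condition: str
    source: str = "z1_samples"
    seed: int | None = None
    unit_ids: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite response values")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


# ---------------------------------------------------------------------------


def encode(image, model):
    """q(Z2 | image) parameters and a map z2 -> q(Z1 | image, Z2) parameters.

    The returned callable accepts a (n, dim_z2) array of Z2 values and
    yields (loc, scale) of the conditional Z1 posterior; the shared
    feed-forward layer is computed once.
    """
    from ._autodiff import Tensor

    x = np.atleast_2d(np.asarray(image, dtype=np.float64))
    lx = model.encode_lx(x)
    if not model.hierarchical:
        loc, sc = model.encode_z1(x)
        return None, lambda z2=None: (loc, sc)
    mu2, s2 = model.encode_z2(x)

    def conditional(z2):
        z2 = np.atleast_2d(np.asarray(z2))
        lx_rep = np.broadcast_to(lx, (z2.shape[0], lx.shape[1]))
        loc, sc = model._q_z1(Tensor(np.ascontiguousarray(lx_rep)), Tensor(z2))
        return loc.data, sc.data

    return (mu2[0], s2[0]), conditional


def _z1_family_sampler(model, rng, loc, scale, n):
    if model.q_family_z1 == "laplace":
        return loc + scale * dists.laplace_noise(rng, (n,) + loc.shape)
    return loc + scale * rng.standard_normal((n,) + loc.shape)


def sample_responses(image, model, scheme: WindowScheme = WindowScheme(),
                     n_trials: int = 100, condition: str = "intact",
                     seed: int = 0, units=None) -> ResponseMatrix:
    """Windowed sampled responses to one stimulus (or a stack of stimuli).

    Per trial: draw `scheme.n_z2_draws` Z2 values from the condition's Z2
    source, draw `scheme.n_z1_per_z2` Z1 values under each, and aggregate
    by the mean.  Returns a units x trials (x stimuli) ResponseMatrix.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; "
                         f"expected one of {CONDITIONS}")
    image = np.asarray(image, dtype=np.float64)
    stack = image.ndim == 2
    images = image if stack else image[None]
    rng = np.random.default_rng(seed)
    per_stim = []
    for x in images:
        per_stim.append(_sample_one(x, model, scheme, n_trials, condition,
                                    rng, units))
    values = np.stack(per_stim, axis=-1)
    if not stack:
        values = values[..., 0]
    return ResponseMatrix(values, scheme=scheme, condition=condition,
                          seed=seed,
                          unit_ids=None if units is None else np.asarray(units))


def _sample_one(x, model, scheme, n_trials, condition, rng, units):
    nz2, nz1 = scheme.n_z2_draws, scheme.n_z1_per_z2
    if not model.hierarchical:
        if condition != "intact":
            raise ValueError("non-hierarchical models support only 'intact'")
        loc, sc = model.encode_z1(x[None])
        draws = _z1_family_sampler(model, rng, loc[0], sc[0],
                                   n_trials * nz2 * nz1)
        resp = draws.reshape(n_trials, nz2 * nz1, -1).mean(axis=1)
        return _select(resp, units).T
    (mu2, s2), conditional = encode(x, model)
    m = n_trials * nz2
    if condition == "intact":
        z2 = mu2 + s2 * rng.standard_normal((m, mu2.size))
    elif condition in ("prior_z2", "prior_both"):
        z2 = rng.standard_normal((m, mu2.size))
    elif condition == "clamp_z2_zero":
        z2 = np.zeros((m, mu2.size))
    if condition == "prior_both":
        loc, sc = model.conditional_prior(z2)
    else:
        loc, sc = conditional(z2)
    draws = loc[None] + sc[None] * (
        dists.laplace_noise(rng, (nz1,) + loc.shape)
        if model.q_family_z1 == "laplace"
        else rng.standard_normal((nz1,) + loc.shape)
    )
    resp = draws.mean(axis=0).reshape(n_trials, nz2, -1).mean(axis=1)
    return _select(resp, units).T


def _select(resp, units):
    return resp if units is None else resp[:, np.asarray(units)]


def marginal_z1_mean(image, model, n_mc: int = 100, seed: int = 0,
                     condition: str = "intact", units=None):
    """Marginal Z1 posterior mean and across-Z2 covariance of the locations.

    The covariance is computed across the conditional locations produced by
    different Z2 draws: it isolates the covariability induced by the
    top-down pathway and excludes the private (conditional-scale)
    variability of individual units.  With Z2 clamped (or a zero-scale Z2
    posterior) the off-diagonal covariance is exactly zero.
    """
    if n_mc < 2:
        raise ValueError("n_mc must be >= 2")
    rng = np.random.default_rng(seed)
    x = np.asarray(image, dtype=np.float64)
    if not model.hierarchical:
        loc, _ = model.encode_z1(x[None])
        loc = _select(loc, units)[0]
        return loc, np.zeros((loc.size, loc.size))
    (mu2, s2), conditional = encode(x, model)
    if condition == "intact":
        z2 = mu2 + s2 * rng.standard_normal((n_mc, mu2.size))
    elif condition == "prior_z2":
        z2 = rng.standard_normal((n_mc, mu2.size))
    elif condition == "clamp_z2_zero":
        z2 = np.zeros((n_mc, mu2.size))
    else:
        raise ValueError(f"unsupported condition {condition!r}")
    locs, _ = conditional(z2)
    locs = _select(locs, units)
    mean = locs.mean(axis=0)
    centered = locs - mean
    cov = centered.T @ centered / (n_mc - 1)
    return mean, cov


def snis_weights(log_weights):
    """Normalized SNIS weights with max-subtraction and discard-max rule.

    The single largest-weight sample is dropped before normalization.
    Returns (keep mask, normalized weights over kept samples, effective
    sample size).
    """
    lw = np.asarray(log_weights, dtype=np.float64)
    keep = np.ones(lw.size, dtype=bool)
    keep[int(np.argmax(lw))] = False
    lw = lw[keep]
    lw = lw - lw.max()
    w = np.exp(lw)
    w = w / w.sum()
    return keep, w, float(1.0 / np.sum(w**2))


def snis_generative_posterior(image, model, n_samples: int = 10_000,
                              seed: int = 0, units=None,
                              compute_correlations: bool = True):
    """Generative-posterior moments by self-normalized importance sampling.

    Proposal: the joint variational posterior.  Log-weights are
    max-subtracted; the single largest-weight sample is discarded before
    normalization (guarding against weight collapse).  Returns a dict with
    Z1/Z2 means, optional Z1 pairwise correlations over `units`, and the
    effective sample size; `ess_warning` flags ESS < 10.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(image, dtype=np.float64)
    D = x.size
    A, b, s_obs = model.A_.data, model.b_.data, model.sigma_obs
    if model.hierarchical:
        (mu2, s2), conditional = encode(x, model)
        z2 = mu2 + s2 * rng.standard_normal((n_samples, mu2.size))
        loc1, b1 = conditional(z2)
        z1 = _z1_family_sampler(model, rng, np.zeros_like(loc1), np.ones_like(b1), 1)[0] * b1 + loc1
        locp, bp = model.conditional_prior(z2)
        log_p = (_obs_loglik(x, z1, A, b, s_obs)
                 + dists.laplace_logpdf(z1, locp, bp).sum(axis=-1)
                 + dists.gaussian_logpdf(z2, 0.0, 1.0).sum(axis=-1))
        log_q = (dists.gaussian_logpdf(z2, mu2, s2).sum(axis=-1)
                 + _q_z1_logpdf(model, z1, loc1, b1))
    else:
        loc1, b1 = model.encode_z1(x[None])
        loc1 = np.broadcast_to(loc1, (n_samples, loc1.shape[1]))
        b1 = np.broadcast_to(b1, loc1.shape)
        z1 = _z1_family_sampler(model, rng, loc1[0], b1[0], n_samples)
        z2 = None
        log_p = (_obs_loglik(x, z1, A, b, s_obs)
                 + dists.laplace_logpdf(z1, 0.0, 1.0).sum(axis=-1))
        log_q = _q_z1_logpdf(model, z1, loc1, b1)
    keep, w, ess = snis_weights(log_p - log_q)
    out = {
        "z1_mean": w @ z1[keep],
        "z2_mean": None if z2 is None else w @ z2[keep],
        "ess": float(ess),
        "ess_warning": bool(ess < 10),
    }
    if out["ess_warning"]:
        warnings.warn(f"SNIS effective sample size is low ({ess:.1f})")
    if compute_correlations:
        zu = _select(z1[keep], units)
        mu = w @ zu
        c = zu - mu
        cov = (c * w[:, None]).T @ c / max(1.0 - np.sum(w**2), 1e-12)
        sd = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
        out["z1_corr"] = cov / np.outer(sd, sd)
    return out


def _obs_loglik(x, z1, A, b, s_obs):
    resid = x[None, :] - (z1 @ A + b)
    D = x.size
    return (-0.5 * D * np.log(2 * np.pi * s_obs**2)
            - np.sum(resid**2, axis=-1) / (2 * s_obs**2))


def _q_z1_logpdf(model, z1, loc, scale):
    if model.q_family_z1 == "laplace":
        return dists.laplace_logpdf(z1, loc, scale).sum(axis=-1)
    return dists.gaussian_logpdf(z1, loc, scale).sum(axis=-1)
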
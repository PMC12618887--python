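"""The three variational autoencoder variants of the V1/V2 model family.

All variants share the generative observation model

    p(image | Z1) = N(image; A Z1 + b, sigma_obs^2 I)

with an overcomplete Z1 layer under a sparse (Laplace) prior.  The
hierarchical variants add a second latent layer Z2 with a standard-normal
prior and a conditional prior p(Z1 | Z2) whose location and scale are
emitted by an MLP (depth 0 gives the linear-integration family, 1 the
shallow and 2 the deep conditional nonlinearity).

* :class:`ShallowVAE` -- single-layer baseline: q(Z1 | image), KL against
  the fixed Laplace prior.
* :class:`FeedForwardVAE` -- hierarchical model with a feed-forward
  posterior factorization q(Z2 | Z1) q(Z1 | image); the objective carries a
  reconstruction term, the conditional-prior cross term, the entropy of
  q(Z1 | image), and the Z2 KL.
* :class:`TopDownVAE` -- hierarchical model with top-down posterior
  factorization q(Z1 | image, Z2) q(Z2 | image), the main model.  Its
  recognition model comprises four MLPs: Z1-ff (image -> shared layer L_x),
  Z2-ff (L_x -> q(Z2|image)), Z1-TD (Z2 -> L_z), and Z1-INT
  (concat(L_x, L_z) -> q(Z1|image,Z2)).

Estimators follow sklearn conventions: ``fit(X)`` trains on whitened
patches (rows), ``transform(X)`` returns marginal Z1 posterior means,
``score(X)`` the mean ELBO.  Training uses Adam with minibatches, an
optional beta factor on the final KL term held low early and ramped
linearly to 1 (beta annealing), gradient clipping, and update skipping.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import dists
from ._autodiff import Tensor, concat
from .nn import MLP, Adam, LocScaleHead, init_linear

__all__ = [
    "ShallowVAE",
    "FeedForwardVAE",
    "TopDownVAE",
    "observation_log_likelihood",
    "kl_or_entropy_terms",
    "identify_active_units",
    "save_model",
    "load_model",
]


# ---------------------------------------------------------------------------
# stand-alone operations


def observation_log_likelihood(image, z1, A, b, sigma_obs):
    """Log N(image; A z1 + b, sigma_obs^2 I), summed over pixels.

    Accepts single vectors or batches (leading axis).
    """
    image = np.asarray(image, dtype=np.float64)
    z1 = np.asarray(z1, dtype=np.float64)
    if not (np.all(np.isfinite(image)) and np.all(np.isfinite(z1))):
        raise ValueError("non-finite inputs")
    pred = z1 @ np.asarray(A).T + np.asarray(b)
    resid = image - pred
    D = image.shape[-1]
    return (-0.5 * D * np.log(2 * np.pi * sigma_obs**2)
            - np.sum(resid**2, axis=-1) / (2 * sigma_obs**2))


def kl_or_entropy_terms(kind, params_q, params_p=None, n_mc=None, seed=0):
    """Closed-form KL/entropy where available, Monte Carlo otherwise.

    kind: 'gaussian_kl', 'laplace_kl', 'gaussian_entropy',
    'laplace_entropy', or 'mc_kl_gaussian' / 'mc_kl_laplace' (reparameterized
    n_mc-sample estimate of KL(q || p) for arbitrary (logpdf-able) p given
    as (loc, scale) of the same family).
    Scales must be strictly positive.  Returns the summed value.
    """
    for p in (params_q, params_p):
        if p is not None and len(p) == 2 and np.any(np.asarray(p[1]) <= 0):
            raise ValueError("non-positive scale")
    if kind == "gaussian_entropy":
        return float(np.sum(dists.gaussian_entropy(np.asarray(params_q[1]))))
    if kind == "laplace_entropy":
        return float(np.sum(dists.laplace_entropy(np.asarray(params_q[1]))))
    mu_q, s_q = map(np.asarray, params_q)
    mu_p, s_p = map(np.asarray, params_p)
    if kind == "gaussian_kl":
        return float(np.sum(dists.gaussian_kl(mu_q, s_q, mu_p, s_p)))
    if kind == "laplace_kl":
        return float(np.sum(dists.laplace_kl(mu_q, s_q, mu_p, s_p)))
    rng = np.random.default_rng(seed)
    n_mc = n_mc or 1
    if kind == "mc_kl_gaussian":
        z = dists.sample_gaussian(rng, mu_q, s_q, size=n_mc)
        lq = dists.gaussian_logpdf(z, mu_q, s_q)
        lp = dists.gaussian_logpdf(z, mu_p, s_p)
    elif kind == "mc_kl_laplace":
        z = dists.sample_laplace(rng, mu_q, s_q, size=n_mc)
        lq = dists.laplace_logpdf(z, mu_q, s_q)
        lp = dists.laplace_logpdf(z, mu_p, s_p)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return float(np.mean(np.sum(lq - lp, axis=tuple(range(1, z.ndim)))))


# ---------------------------------------------------------------------------
# tensor-space density helpers (autodiff path)


def _t_gauss_kl_std(mu: Tensor, sigma: Tensor) -> Tensor:
    return (mu**2 + sigma**2 - 1.0) * 0.5 - sigma.log()


def _t_laplace_kl(mu1, b1, mu2, b2) -> Tensor:
    d = (mu1 - mu2).abs()
    return (b2 / b1).log() + (b1 * ((-(d / b1)).exp()) + d) / b2 - 1.0


def _t_laplace_kl_std(mu1, b1) -> Tensor:
    # against La(0, 1)
    d = mu1.abs()
    return -(b1.log()) + b1 * ((-(d / b1)).exp()) + d - 1.0


def _t_gauss_kl(mu1, s1, mu2, s2) -> Tensor:
    return (s2 / s1).log() + (s1**2 + (mu1 - mu2) ** 2) / (s2**2 * 2.0) - 0.5


def _t_laplace_logpdf(x, loc, scale) -> Tensor:
    return -((scale * 2.0).log()) - (x - loc).abs() / scale


def _t_laplace_entropy(b) -> Tensor:
    return (b * 2.0).log() + 1.0


def _t_recon(x: Tensor, z1: Tensor, A: Tensor, b: Tensor, sigma_obs: float) -> Tensor:
    D = x.shape[-1]
    resid = x - (z1 @ A + b)  # A stored as (dim_z1, D)
    return (resid**2).sum(axis=-1) / (-2.0 * sigma_obs**2) + (
        -0.5 * D * np.log(2 * np.pi * sigma_obs**2)
    )


# ---------------------------------------------------------------------------
# estimators


class _BaseVAE(TransformerMixin, BaseEstimator):
    """Shared machinery: generative map, training loop, scoring."""

    kind = "base"

    def __init__(self, dim_z1=160, dim_z2=12, lx_width=128, td_width=32,
                 int_hidden=0, z2_hidden=0, cond_hidden=32, cond_depth=2,
                 sigma_obs=0.4, q_family_z1="laplace", shared_encoder=True,
                 lr=1e-3, lr_segments=None, n_epochs=100, batch_size=128,
                 beta0=0.1, beta_hold_epochs=1000, beta_ramp_epochs=1800,
                 beta_final_segments=None, clip_factor=20.0, skip_factor=50.0,
                 transform_n_mc=10, train_dtype="float32", random_state=0):
        self.dim_z1 = dim_z1
        self.dim_z2 = dim_z2
        self.lx_width = lx_width
        self.td_width = td_width
        self.int_hidden = int_hidden
        self.z2_hidden = z2_hidden
        self.cond_hidden = cond_hidden
        self.cond_depth = cond_depth
        self.sigma_obs = sigma_obs
        self.q_family_z1 = q_family_z1
        self.shared_encoder = shared_encoder
        self.lr = lr
        self.lr_segments = lr_segments
        self.n_epochs = n_epochs
        self.batch_size = batch_size
        self.beta0 = beta0
        self.beta_hold_epochs = beta_hold_epochs
        self.beta_ramp_epochs = beta_ramp_epochs
        self.beta_final_segments = beta_final_segments
        self.clip_factor = clip_factor
        self.skip_factor = skip_factor
        self.transform_n_mc = transform_n_mc
        self.train_dtype = train_dtype
        self.random_state = random_state

    # -- architecture -------------------------------------------------------

    @property
    def hierarchical(self) -> bool:
        return self.kind in ("ffvae", "tdvae") and self.dim_z2 > 0

    def _build(self, D, rng):
        if self.sigma_obs <= 0:
            raise ValueError("sigma_obs must be positive")
        self.n_features_in_ = D
        self.edge_ = int(round(np.sqrt(D)))
        # generative map: A stored transposed (dim_z1, D) for row-batch matmuls
        self.A_ = Tensor(rng.normal(0, 0.1, size=(self.dim_z1, D)), requires_grad=True)
        self.b_ = Tensor(np.zeros(D), requires_grad=True)
        params = [self.A_, self.b_]
        # shared feed-forward layer L_x and the Z1 posterior head
        self.z1_ff_ = MLP(rng, [D, self.lx_width], final_activation=True)
        params += self.z1_ff_.params
        int_in = self.lx_width + (self.td_width if self._has_td() else 0)
        if self.int_hidden:
            self.z1_int_mlp_ = MLP(rng, [int_in, self.int_hidden],
                                   final_activation=True)
            params += self.z1_int_mlp_.params
            head_in = self.int_hidden
        else:
            self.z1_int_mlp_ = None
            head_in = int_in
        self.z1_head_ = LocScaleHead(rng, head_in, self.dim_z1)
        params += self.z1_head_.params
        if self.hierarchical:
            if self.kind == "tdvae":
                z2_in = self.lx_width
                if not self.shared_encoder:
                    self.z2_ff_in_ = MLP(rng, [D, self.lx_width],
                                         final_activation=True)
                    params += self.z2_ff_in_.params
                else:
                    self.z2_ff_in_ = None
            else:  # ffvae encodes Z2 from a Z1 sample
                z2_in = self.dim_z1
                self.z2_ff_in_ = MLP(rng, [z2_in, self.lx_width],
                                     final_activation=True)
                params += self.z2_ff_in_.params
                z2_in = self.lx_width
            if self.z2_hidden:
                self.z2_mlp_ = MLP(rng, [z2_in, self.z2_hidden],
                                   final_activation=True)
                params += self.z2_mlp_.params
                z2_in = self.z2_hidden
            else:
                self.z2_mlp_ = None
            self.z2_head_ = LocScaleHead(rng, z2_in, self.dim_z2)
            params += self.z2_head_.params
            if self._has_td():
                self.z1_td_ = MLP(rng, [self.dim_z2, self.td_width],
                                  final_activation=True)
                params += self.z1_td_.params
            # conditional prior p(Z1 | Z2)
            sizes = [self.dim_z2] + [self.cond_hidden] * self.cond_depth
            if self.cond_depth:
                self.cond_mlp_ = MLP(rng, sizes, final_activation=True)
                params += self.cond_mlp_.params
                cond_in = sizes[-1]
            else:
                self.cond_mlp_ = None
                cond_in = self.dim_z2
            self.cond_head_ = LocScaleHead(rng, cond_in, self.dim_z1)
            params += self.cond_head_.params
        self.params_ = params

    def _has_td(self):
        return self.kind == "tdvae" and self.dim_z2 > 0

    # -- forward passes (tensor space) --------------------------------------

    def _lx(self, x: Tensor) -> Tensor:
        return self.z1_ff_(x)

    def _q_z2_from(self, h: Tensor):
        if self.z2_mlp_ is not None:
            h = self.z2_mlp_(h)
        return self.z2_head_(h)

    def _q_z1(self, lx: Tensor, z2: Tensor | None):
        if self._has_td() and z2 is not None:
            lz = self.z1_td_(z2)
            h = concat([lx, lz], axis=-1)
        else:
            h = lx
        if self.z1_int_mlp_ is not None:
            h = self.z1_int_mlp_(h)
        return self.z1_head_(h)

    def _cond_prior(self, z2: Tensor):
        h = self.cond_mlp_(z2) if self.cond_mlp_ is not None else z2
        return self.cond_head_(h)

    @staticmethod
    def _noise_dtype():
        from . import _autodiff

        return (np.float32 if _autodiff.DEFAULT_DTYPE == np.float32
                else np.float64)

    def _sample_z1(self, loc: Tensor, scale: Tensor, rng):
        if self.q_family_z1 == "laplace":
            c = dists.laplace_noise(rng, loc.shape, dtype=self._noise_dtype())
        elif self.q_family_z1 == "normal":
            c = rng.standard_normal(loc.shape, dtype=self._noise_dtype())
        else:
            raise ValueError("q_family_z1 must be 'laplace' or 'normal'")
        return loc + scale * Tensor(c)

    def _kl_z1(self, loc_q, scale_q, loc_p=None, scale_p=None, z1=None):
        """Per-sample summed Z1 divergence term appropriate for the family."""
        if loc_p is None:  # fixed standard-Laplace prior
            if self.q_family_z1 == "laplace":
                return _t_laplace_kl_std(loc_q, scale_q).sum(axis=-1)
            # normal q against Laplace(0,1): single-sample MC
            lq = -0.5 * np.log(2 * np.pi) - (scale_q.log()) - ((z1 - loc_q) ** 2) / (
                scale_q**2 * 2.0
            )
            lp = _t_laplace_logpdf(z1, Tensor(0.0), Tensor(1.0))
            return (lq - lp).sum(axis=-1)
        if self.q_family_z1 == "laplace":
            return _t_laplace_kl(loc_q, scale_q, loc_p, scale_p).sum(axis=-1)
        lq = -0.5 * np.log(2 * np.pi) - scale_q.log() - ((z1 - loc_q) ** 2) / (
            scale_q**2 * 2.0
        )
        lp = _t_laplace_logpdf(z1, loc_p, scale_p)
        return (lq - lp).sum(axis=-1)

    # -- objective -----------------------------------------------------------

    def _elbo_terms(self, x: Tensor, rng, beta=1.0):
        raise NotImplementedError

    def elbo(self, X, n_mc=1, seed=0, beta=1.0):
        """Monte Carlo ELBO averaged over rows of X; returns (value, terms)."""
        check_is_fitted(self, "params_")
        rng = np.random.default_rng(seed)
        x = Tensor(np.atleast_2d(np.asarray(X, dtype=np.float64)))
        totals: dict[str, float] = {}
        val = 0.0
        for _ in range(n_mc):
            t, terms = self._elbo_terms(x, rng, beta=beta)
            val += float(t.data) / n_mc
            for k, v in terms.items():
                totals[k] = totals.get(k, 0.0) + float(v.data) / n_mc
        return val, totals

    # -- training ------------------------------------------------------------

    def _beta(self, epoch: int) -> float:
        """KL weight: hold at beta0, ramp linearly to 1, then optional
        replayed segments (e.g. a temporary compression spike above 1)."""
        if self.kind == "shallow":
            return 1.0
        if epoch < self.beta_hold_epochs:
            return self.beta0
        ramp = (epoch - self.beta_hold_epochs) / max(self.beta_ramp_epochs, 1)
        if ramp < 1.0:
            return self.beta0 + (1.0 - self.beta0) * ramp
        if self.beta_final_segments:
            e = epoch - self.beta_hold_epochs - self.beta_ramp_epochs
            acc = 0
            for beta, n in self.beta_final_segments:
                acc += n
                if e < acc:
                    return beta
        return 1.0

    def _lr_at(self, epoch: int) -> float:
        segments = self.lr_segments or [(self.lr, self.n_epochs)]
        acc = 0
        for lr, n in segments:
            acc += n
            if epoch < acc:
                return lr
        return segments[-1][0]

    def fit(self, X, y=None, X_val=None):
        from ._autodiff import default_dtype

        with default_dtype(self.train_dtype):
            return self._fit_impl(X, X_val)

    def _fit_impl(self, X, X_val):
        X = np.asarray(X, dtype=np.float64)
        n, D = X.shape
        rng = np.random.default_rng(self.random_state)
        self._build(D, rng)
        opt = Adam(self.params_, lr=self.lr, clip_factor=self.clip_factor,
                   skip_factor=self.skip_factor)
        n_epochs = sum(n for _, n in self.lr_segments) if self.lr_segments \
            else self.n_epochs
        history = {"train_elbo": [], "val_elbo": [], "beta": []}
        checkpoint = [p.data.copy() for p in self.params_]
        n_batches = max(1, n // self.batch_size)
        for epoch in range(n_epochs):
            beta = self._beta(epoch)
            opt.lr = self._lr_at(epoch)
            perm = rng.permutation(n)
            ep_loss = 0.0
            for bi in range(n_batches):
                rows = perm[bi * self.batch_size:(bi + 1) * self.batch_size]
                x = Tensor(X[rows])
                elbo_t, _ = self._elbo_terms(x, rng, beta=beta)
                loss = -elbo_t
                if not np.isfinite(loss.data):
                    warnings.warn("NaN loss: aborting, restoring last checkpoint")
                    for p, d in zip(self.params_, checkpoint):
                        p.data = d
                    self.history_ = history
                    return self
                loss.backward()
                opt.step()
                ep_loss += float(elbo_t.data)
            history["train_elbo"].append(ep_loss / n_batches)
            history["beta"].append(beta)
            if X_val is not None:
                val, _ = self.elbo(X_val[: min(len(X_val), 512)],
                                   seed=self.random_state + epoch)
                history["val_elbo"].append(val)
            checkpoint = [p.data.copy() for p in self.params_]
        self.history_ = history
        self.n_clipped_ = opt.n_clipped
        self.n_skipped_ = opt.n_skipped
        return self

    # -- inference-side numpy passes -----------------------------------------

    def encode_lx(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("dimension mismatch with fitted model")
        return self._lx(Tensor(X)).data

    def encode_z2(self, X):
        """Parameters (mu, sigma) of q(Z2 | image)."""
        if not self.hierarchical:
            raise ValueError("model has no Z2 layer")
        if self.kind == "tdvae":
            h = self.z2_ff_in_ if self.z2_ff_in_ is not None else None
            base = (h(Tensor(np.atleast_2d(X))) if h is not None
                    else Tensor(self.encode_lx(X)))
        else:
            # feed-forward variant: Z2 encoded from the Z1 posterior mean
            loc1, _ = self.encode_z1(X, None)
            base = self.z2_ff_in_(Tensor(loc1))
        mu, sg = self._q_z2_from(base)
        return mu.data, sg.data

    def encode_z1(self, X, z2=None):
        """Parameters (loc, scale) of q(Z1 | image[, Z2])."""
        lx = Tensor(self.encode_lx(X))
        zt = None if z2 is None else Tensor(np.atleast_2d(np.asarray(z2)))
        loc, sc = self._q_z1(lx, zt)
        return loc.data, sc.data

    def conditional_prior(self, z2):
        """Parameters (loc, scale) of p(Z1 | Z2)."""
        if not self.hierarchical:
            raise ValueError("model has no Z2 layer")
        loc, sc = self._cond_prior(Tensor(np.atleast_2d(np.asarray(z2))))
        return loc.data, sc.data

    def decode(self, z1):
        """Generated mean image A z1 + b."""
        check_is_fitted(self, "params_")
        return np.atleast_2d(np.asarray(z1)) @ self.A_.data + self.b_.data

    def posterior_mean_z1(self, X, n_mc=None, seed=0):
        """Marginal Z1 posterior mean (MC over Z2 for hierarchical models)."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if not self.hierarchical:
            return self.encode_z1(X)[0]
        n_mc = n_mc or self.transform_n_mc
        rng = np.random.default_rng(seed)
        mu2, s2 = self.encode_z2(X)
        lx = self.encode_lx(X)
        acc = np.zeros((X.shape[0], self.dim_z1))
        for _ in range(n_mc):
            z2 = mu2 + s2 * rng.standard_normal(mu2.shape)
            loc, _ = self._q_z1(Tensor(lx), Tensor(z2))
            acc += loc.data
        return acc / n_mc

    def transform(self, X):
        return self.posterior_mean_z1(X, seed=0)

    def reconstruct(self, X):
        """A (posterior mean of Z1) + b."""
        return self.decode(self.posterior_mean_z1(X, seed=0))

    def score(self, X, y=None):
        return self.elbo(X, seed=0)[0] / len(np.atleast_2d(X))


class ShallowVAE(_BaseVAE):
    """Non-hierarchical sparse-coding VAE: q(Z1 | image) against La(0, 1)."""

    kind = "shallow"

    def __init__(self, dim_z1=160, lx_width=128, int_hidden=0, sigma_obs=0.4,
                 q_family_z1="laplace", lr=1e-3, lr_segments=None, n_epochs=100,
                 batch_size=128, clip_factor=20.0, skip_factor=50.0,
                 transform_n_mc=10, train_dtype="float32", random_state=0):
        super().__init__(dim_z1=dim_z1, dim_z2=0, lx_width=lx_width,
                         int_hidden=int_hidden, sigma_obs=sigma_obs,
                         q_family_z1=q_family_z1, lr=lr, lr_segments=lr_segments,
                         n_epochs=n_epochs, batch_size=batch_size,
                         clip_factor=clip_factor, skip_factor=skip_factor,
                         transform_n_mc=transform_n_mc,
                         train_dtype=train_dtype, random_state=random_state)

    def _elbo_terms(self, x, rng, beta=1.0):
        lx = self._lx(x)
        loc, scale = self._q_z1(lx, None)
        z1 = self._sample_z1(loc, scale, rng)
        recon = _t_recon(x, z1, self.A_, self.b_, self.sigma_obs).mean()
        kl1 = self._kl_z1(loc, scale, z1=z1).mean()
        elbo = recon - kl1 * beta
        return elbo, {"recon": recon, "kl_z1": kl1}


class FeedForwardVAE(_BaseVAE):
    """Hierarchical VAE with feed-forward posterior q(Z2 | Z1) q(Z1 | image)."""

    kind = "ffvae"

    def _elbo_terms(self, x, rng, beta=1.0):
        lx = self._lx(x)
        loc1, b1 = self._q_z1(lx, None)
        z1 = self._sample_z1(loc1, b1, rng)
        mu2, s2 = self._q_z2_from(self.z2_ff_in_(z1))
        z2 = mu2 + s2 * Tensor(rng.standard_normal(mu2.shape, dtype=self._noise_dtype()))
        locp, bp = self._cond_prior(z2)
        recon = _t_recon(x, z1, self.A_, self.b_, self.sigma_obs).mean()
        cross = _t_laplace_logpdf(z1, locp, bp).sum(axis=-1).mean()
        ent = _t_laplace_entropy(b1).sum(axis=-1).mean()
        kl2 = _t_gauss_kl_std(mu2, s2).sum(axis=-1).mean()
        elbo = recon + cross + ent - kl2 * beta
        return elbo, {"recon": recon, "cross": cross, "entropy": ent,
                      "kl_z2": kl2}


class TopDownVAE(_BaseVAE):
    """Hierarchical VAE with top-down posterior q(Z1|image,Z2) q(Z2|image)."""

    kind = "tdvae"

    def _elbo_terms(self, x, rng, beta=1.0):
        lx = self._lx(x)
        if self.dim_z2 > 0:
            base = self.z2_ff_in_(x) if self.z2_ff_in_ is not None else lx
            mu2, s2 = self._q_z2_from(base)
            z2 = mu2 + s2 * Tensor(rng.standard_normal(mu2.shape, dtype=self._noise_dtype()))
            loc1, b1 = self._q_z1(lx, z2)
            z1 = self._sample_z1(loc1, b1, rng)
            locp, bp = self._cond_prior(z2)
            recon = _t_recon(x, z1, self.A_, self.b_, self.sigma_obs).mean()
            kl1 = self._kl_z1(loc1, b1, locp, bp, z1=z1).mean()
            kl2 = _t_gauss_kl_std(mu2, s2).sum(axis=-1).mean()
            elbo = recon - kl1 - kl2 * beta
            return elbo, {"recon": recon, "kl_z1": kl1, "kl_z2": kl2}
        # degenerate hierarchy: collapses to the shallow objective
        loc1, b1 = self._q_z1(lx, None)
        z1 = self._sample_z1(loc1, b1, rng)
        recon = _t_recon(x, z1, self.A_, self.b_, self.sigma_obs).mean()
        kl1 = self._kl_z1(loc1, b1, z1=z1).mean()
        return recon - kl1 * beta, {"recon": recon, "kl_z1": kl1}


# ---------------------------------------------------------------------------
# active-unit identification


def _two_means_1d(x: np.ndarray):
    """2-means clustering of a 1-D array; returns (mask_high, gap)."""
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.ones_like(x, dtype=bool), 0.0
    c0, c1 = lo, hi
    for _ in range(100):
        assign = np.abs(x - c1) < np.abs(x - c0)
        if assign.all() or (~assign).all():
            break
        n0, n1 = c0, c1
        c0, c1 = x[~assign].mean(), x[assign].mean()
        if np.isclose(n0, c0) and np.isclose(n1, c1):
            break
    assign = np.abs(x - c1) < np.abs(x - c0)
    if assign.all() or (~assign).all():
        return np.ones_like(x, dtype=bool), 0.0
    spread = max(x[assign].std(), x[~assign].std(), 1e-12)
    gap = (x[assign].mean() - x[~assign].mean()) / spread
    return assign, gap


def identify_active_units(model, X_test, layer="z1", sta_fields=None,
                          projective_fields=None, n_mc=5, seed=0,
                          min_gap=2.0):
    """Partition latent units into active/inactive by four criteria.

    Criteria: (1) variance of posterior-mean responses across test images,
    (2) mean posterior variance, (3) mean squared receptive-field (STA)
    pixel intensity, (4) mean squared projective-field pixel intensity.
    Each statistic is 2-means clustered in the log domain.  Active units
    occupy the high cluster for criteria 1, 3 and 4; for criterion 2 a
    collapsed unit's posterior width matches the prior's, so the active
    cluster is the one whose mean log-variance lies farther from the
    prior variance.  The consensus (majority vote) active set is returned
    together with per-criterion masks and disagreement counts.  A
    criterion whose two clusters are separated by less than `min_gap`
    pooled standard deviations is treated as unimodal: it votes
    all-active with a warning.
    """
    X_test = np.atleast_2d(np.asarray(X_test, dtype=np.float64))
    rng = np.random.default_rng(seed)
    if layer == "z1":
        if model.hierarchical:
            mu2, s2 = model.encode_z2(X_test)
            lx = model.encode_lx(X_test)
            locs, var_acc = 0.0, 0.0
            for _ in range(n_mc):
                z2 = mu2 + s2 * rng.standard_normal(mu2.shape)
                loc, sc = model._q_z1(Tensor(lx), Tensor(z2))
                locs = locs + loc.data / n_mc
                var_acc = var_acc + _scale_to_var(model, sc.data) / n_mc
            means, post_var = locs, var_acc
        else:
            loc, sc = model.encode_z1(X_test)
            means, post_var = loc, _scale_to_var(model, sc)
    elif layer == "z2":
        mu2, s2 = model.encode_z2(X_test)
        means, post_var = mu2, s2**2
    else:
        raise ValueError("layer must be 'z1' or 'z2'")
    stats_list = [means.var(axis=0), post_var.mean(axis=0)]
    names = ["response_variance", "posterior_variance"]
    if sta_fields is not None:
        stats_list.append(np.mean(np.asarray(sta_fields) ** 2, axis=tuple(
            range(1, np.asarray(sta_fields).ndim))))
        names.append("sta_energy")
    if projective_fields is not None:
        stats_list.append(np.mean(np.asarray(projective_fields) ** 2, axis=tuple(
            range(1, np.asarray(projective_fields).ndim))))
        names.append("projective_energy")
    # prior variance reference for the posterior-width criterion
    if layer == "z2":
        prior_var = 1.0
    else:
        prior_var = 2.0  # Laplace(0, 1) prior variance
    masks = {}
    for name, s in zip(names, stats_list):
        logs = np.log10(np.maximum(s, 1e-300))
        mask, gap = _two_means_1d(logs)
        if gap < min_gap:
            warnings.warn(f"criterion {name}: statistic looks unimodal; "
                          "treating all units as active")
            mask = np.ones(len(s), dtype=bool)
        elif name == "posterior_variance":
            ref = np.log10(prior_var)
            hi = abs(logs[mask].mean() - ref)
            lo = abs(logs[~mask].mean() - ref)
            if lo > hi:
                mask = ~mask
        masks[name] = mask
    votes = np.sum(list(masks.values()), axis=0)
    consensus = votes * 2 > len(masks)  # strict majority
    disagreements = {n: int(np.sum(m != consensus)) for n, m in masks.items()}
    return consensus, masks, disagreements


def _scale_to_var(model, scale):
    # Laplace variance is 2 b^2; Gaussian is sigma^2
    return 2.0 * scale**2 if model.q_family_z1 == "laplace" else scale**2


# ---------------------------------------------------------------------------
# checkpoint I/O


def save_model(model, path):
    """Serialize a fitted estimator (params + config) to HDF5."""
    import h5py
    import json

    check_is_fitted(model, "params_")
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = model.kind
        f.attrs["config"] = json.dumps(model.get_params())
        f.attrs["n_features_in"] = model.n_features_in_
        for i, p in enumerate(model.params_):
            f.create_dataset(f"param_{i}", data=p.data)


def load_model(path):
    import h5py
    import json

    with h5py.File(path, "r") as f:
        kind = f.attrs["kind"]
        config = json.loads(f.attrs["config"])
        D = int(f.attrs["n_features_in"])
        arrays = [f[f"param_{i}"][()] for i in range(len(
            [k for k in f.keys() if k.startswith("param_")]))]
    cls = {"shallow": ShallowVAE, "ffvae": FeedForwardVAE,
           "tdvae": TopDownVAE}[kind]
    model = cls(**config)
    model._build(D, np.random.default_rng(model.random_state))
    for p, a in zip(model.params_, arrays):
        p.data = a
    model.history_ = {}
    return model
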
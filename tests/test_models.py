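"""VAE objectives: likelihoods, KL terms, ELBO structure and gradients,
training behavior, and active-unit identification."""

import warnings

import numpy as np
import pytest
from scipy import stats as sps

from topdownvae import dists
from topdownvae._autodiff import Tensor, grad_check
from topdownvae.models import (
    FeedForwardVAE,
    ShallowVAE,
    TopDownVAE,
    _two_means_1d,
    identify_active_units,
    kl_or_entropy_terms,
    load_model,
    observation_log_likelihood,
    save_model,
)


def _inv_softplus(y):
    return np.log(np.expm1(y))


def _force_head(head, loc, scale):
    """Zero a LocScaleHead's weights and pin its outputs via the biases."""
    head.loc[0].data[:] = 0.0
    head.loc[1].data[:] = loc
    head.raw_scale[0].data[:] = 0.0
    head.raw_scale[1].data[:] = _inv_softplus(scale - 1e-6)


# ---------------------------------------------------------------------------
# observation likelihood


def test_observation_loglik_zero_residual():
    D = 6
    A = np.random.default_rng(0).standard_normal((D, 3))
    z = np.array([0.3, -1.0, 2.0])
    b = np.ones(D)
    image = A @ z + b
    ll = observation_log_likelihood(image, z, A, b, sigma_obs=0.4)
    np.testing.assert_allclose(ll, -0.5 * D * np.log(2 * np.pi * 0.16))


def test_observation_loglik_scalar_toy():
    # D=1, A=2, b=0, sigma=0.4, z=1, image=2.4: residual/sigma = 1
    ll = observation_log_likelihood(np.array([2.4]), np.array([1.0]),
                                    np.array([[2.0]]), np.array([0.0]), 0.4)
    np.testing.assert_allclose(ll, -0.5 * np.log(2 * np.pi * 0.16) - 0.5)


def test_observation_loglik_batched_equals_loop(rng):
    D, K, n = 5, 3, 7
    A = rng.standard_normal((D, K))
    b = rng.standard_normal(D)
    Z = rng.standard_normal((n, K))
    X = rng.standard_normal((n, D))
    batched = observation_log_likelihood(X, Z, A, b, 0.4)
    looped = [observation_log_likelihood(X[i], Z[i], A, b, 0.4)
              for i in range(n)]
    np.testing.assert_allclose(batched, looped)


def test_observation_loglik_rejects_nonfinite():
    with pytest.raises(ValueError):
        observation_log_likelihood(np.array([np.nan]), np.array([1.0]),
                                   np.array([[1.0]]), np.array([0.0]), 0.4)


# ---------------------------------------------------------------------------
# KL / entropy terms


def test_kl_identical_parameters_is_zero():
    mu, s = np.array([0.4, -1.0]), np.array([0.5, 2.0])
    assert kl_or_entropy_terms("gaussian_kl", (mu, s), (mu, s)) == pytest.approx(0)
    assert kl_or_entropy_terms("laplace_kl", (mu, s), (mu, s)) == pytest.approx(0)


def test_gaussian_kl_closed_form_example():
    # KL(N(1,1) || N(0,1)) = 0.5
    val = kl_or_entropy_terms("gaussian_kl", (np.array([1.0]), np.array([1.0])),
                              (np.array([0.0]), np.array([1.0])))
    assert val == pytest.approx(0.5)


def test_mc_kl_matches_closed_form_within_3_se():
    mu_q, s_q = np.array([0.7]), np.array([1.3])
    mu_p, s_p = np.array([-0.2]), np.array([0.8])
    closed = kl_or_entropy_terms("gaussian_kl", (mu_q, s_q), (mu_p, s_p))
    n = 100_000
    mc = kl_or_entropy_terms("mc_kl_gaussian", (mu_q, s_q), (mu_p, s_p),
                             n_mc=n, seed=11)
    rng = np.random.default_rng(5)
    z = dists.sample_gaussian(rng, mu_q, s_q, size=n)
    per = (dists.gaussian_logpdf(z, mu_q, s_q)
           - dists.gaussian_logpdf(z, mu_p, s_p)).ravel()
    se = per.std() / np.sqrt(n)
    assert abs(mc - closed) < 3 * se


def test_laplace_kl_closed_form_against_mc():
    mu_q, s_q = np.array([0.5]), np.array([0.9])
    mu_p, s_p = np.array([0.0]), np.array([1.4])
    closed = kl_or_entropy_terms("laplace_kl", (mu_q, s_q), (mu_p, s_p))
    mc = kl_or_entropy_terms("mc_kl_laplace", (mu_q, s_q), (mu_p, s_p),
                             n_mc=200_000, seed=3)
    assert abs(mc - closed) < 0.02


def test_entropies_and_scale_validation():
    assert kl_or_entropy_terms("laplace_entropy", (None, np.array([0.5]))) == \
        pytest.approx(1 + np.log(1.0))
    assert kl_or_entropy_terms("gaussian_entropy", (None, np.array([1.0]))) == \
        pytest.approx(0.5 * np.log(2 * np.pi * np.e))
    with pytest.raises(ValueError, match="scale"):
        kl_or_entropy_terms("gaussian_kl", (np.zeros(1), np.zeros(1)),
                            (np.zeros(1), np.ones(1)))


def test_reparameterized_sampling_moments():
    rng = np.random.default_rng(0)
    n = 100_000
    g = dists.sample_gaussian(rng, 0.5, 1.2, size=n)
    assert abs(g.mean() - 0.5) < 3 * 1.2 / np.sqrt(n)
    assert abs(g.var() - 1.44) < 3 * 1.44 * np.sqrt(2 / n)
    la = dists.sample_laplace(rng, -0.3, 0.8, size=n)
    assert abs(la.mean() + 0.3) < 3 * np.sqrt(2 * 0.64 / n)
    assert abs(la.var() - 2 * 0.64) < 4 * 2 * 0.64 * np.sqrt(5 / n)


# ---------------------------------------------------------------------------
# ELBO structure and gradients


@pytest.mark.parametrize("cls,kwargs", [
    (ShallowVAE, dict(dim_z1=3, lx_width=3)),
    (TopDownVAE, dict(dim_z1=3, dim_z2=2, lx_width=3, td_width=2,
                      cond_hidden=2, cond_depth=1)),
    (FeedForwardVAE, dict(dim_z1=3, dim_z2=2, lx_width=3, td_width=2,
                          cond_hidden=2, cond_depth=1)),
])
def test_elbo_gradients_match_finite_differences(cls, kwargs):
    """4-pixel toy models: analytic ELBO gradients vs central differences."""
    model = cls(**kwargs)
    model._build(4, np.random.default_rng(0))
    x = Tensor(np.random.default_rng(1).standard_normal((2, 4)))

    def fn(params):
        rng = np.random.default_rng(42)  # frozen noise: deterministic in params
        elbo, _ = model._elbo_terms(x, rng, beta=0.7)
        return elbo

    assert grad_check(fn, model.params_, eps=1e-5) < 1e-4


def test_shallow_elbo_reduces_to_reconstruction_when_q_equals_prior():
    model = ShallowVAE(dim_z1=2, lx_width=3, q_family_z1="laplace")
    model._build(4, np.random.default_rng(0))
    _force_head(model.z1_head_, 0.0, 1.0)  # q = La(0,1) = prior
    val, terms = model.elbo(np.random.default_rng(1).standard_normal((3, 4)),
                            seed=0)
    assert terms["kl_z1"] == pytest.approx(0.0, abs=1e-9)
    assert val == pytest.approx(terms["recon"])


def test_mc_elbo_matches_conjugate_closed_form():
    """1-latent, 1-pixel linear model with Gaussian q: the ELBO integrates
    in closed form term by term."""
    model = ShallowVAE(dim_z1=1, lx_width=2, q_family_z1="normal")
    model._build(1, np.random.default_rng(0))
    A, b, s_obs = 1.5, 0.3, model.sigma_obs
    mu0, s0 = 0.2, 0.7
    model.A_.data[:] = A
    model.b_.data[:] = b
    _force_head(model.z1_head_, mu0, s0)
    x = 1.1
    # E_q[log p(x|z)] for z ~ N(mu0, s0^2)
    recon = (-0.5 * np.log(2 * np.pi * s_obs**2)
             - ((x - A * mu0 - b) ** 2 + A**2 * s0**2) / (2 * s_obs**2))
    # E_q[log La(z; 0, 1)] = -log 2 - E|z|
    e_abs = (s0 * np.sqrt(2 / np.pi) * np.exp(-mu0**2 / (2 * s0**2))
             + mu0 * (1 - 2 * sps.norm.cdf(-mu0 / s0)))
    cross = -np.log(2) - e_abs
    ent = 0.5 * np.log(2 * np.pi * np.e * s0**2)
    oracle = recon + cross + ent
    n_mc = 4000
    val, _ = model.elbo(np.array([[x]]), n_mc=n_mc, seed=7)
    # SE of the MC estimate from an independent sample of per-draw values
    rng = np.random.default_rng(123)
    z = rng.normal(mu0, s0, size=200_000)
    per = (dists.gaussian_logpdf(x, A * z + b, s_obs)
           + dists.laplace_logpdf(z, 0, 1)
           - dists.gaussian_logpdf(z, mu0, s0))
    se = per.std() / np.sqrt(n_mc)
    assert abs(val - oracle) < 3 * se


def test_tdvae_with_no_z2_collapses_to_shallow():
    X = np.random.default_rng(3).standard_normal((8, 9))
    sh = ShallowVAE(dim_z1=5, lx_width=4, random_state=0)
    td = TopDownVAE(dim_z1=5, dim_z2=0, lx_width=4, random_state=0)
    sh._build(9, np.random.default_rng(0))
    td._build(9, np.random.default_rng(0))
    v1, t1 = sh.elbo(X, seed=5)
    v2, t2 = td.elbo(X, seed=5)
    assert v1 == pytest.approx(v2)
    assert t1["kl_z1"] == pytest.approx(t2["kl_z1"])


def test_tdvae_elbo_agrees_with_generic_two_layer_form():
    """The factorized objective equals the generic ELBO
    E_q[log p(x,z1,z2) - log q(z1,z2|x)] when the KL terms are expanded
    with the top-down factorization -- checked by Monte Carlo."""
    model = TopDownVAE(dim_z1=3, dim_z2=2, lx_width=4, td_width=2,
                       cond_hidden=2, cond_depth=1)
    model._build(6, np.random.default_rng(0))
    x = np.random.default_rng(1).standard_normal(6)
    n = 40_000
    rng = np.random.default_rng(2)
    mu2, s2 = model.encode_z2(x[None])
    z2 = mu2 + s2 * rng.standard_normal((n, 2))
    lx = model.encode_lx(x[None])
    loc1, b1 = model._q_z1(Tensor(np.broadcast_to(lx, (n, lx.shape[1])).copy()),
                           Tensor(z2))
    loc1, b1 = loc1.data, b1.data
    z1 = dists.sample_laplace(rng, loc1, b1)
    locp, bp = model.conditional_prior(z2)
    # paired comparison with identical draws: the reconstruction term is
    # common to both forms and cancels, leaving the KL expansions
    diff = ((dists.laplace_logpdf(z1, locp, bp)
             - dists.laplace_logpdf(z1, loc1, b1)).sum(-1)
            + dists.laplace_kl(loc1, b1, locp, bp).sum(-1)
            + (dists.gaussian_logpdf(z2, 0, 1)
               - dists.gaussian_logpdf(z2, mu2, s2)).sum(-1)
            + dists.gaussian_kl_std((mu2 - 0), s2).sum())
    se = diff.std() / np.sqrt(n)
    assert abs(diff.mean()) < 4 * se


# ---------------------------------------------------------------------------
# training behavior


def test_beta_schedule_values():
    td = TopDownVAE()
    assert td._beta(0) == td._beta(999) == 0.1
    assert td._beta(1000 + 1800) == pytest.approx(1.0)
    assert 0.1 < td._beta(1900) < 1.0
    assert ShallowVAE()._beta(0) == 1.0  # no annealing for the shallow model


def test_lr_segments_replay():
    td = TopDownVAE(lr_segments=[(1e-3, 5), (1e-4, 3)])
    assert td._lr_at(0) == td._lr_at(4) == 1e-3
    assert td._lr_at(5) == td._lr_at(7) == td._lr_at(100) == 1e-4


def test_nonfinite_loss_aborts_and_restores_checkpoint():
    X = np.random.default_rng(0).standard_normal((64, 9)) * 1e160
    model = ShallowVAE(dim_z1=4, lx_width=3, n_epochs=3, random_state=0)
    with pytest.warns(UserWarning, match="NaN"):
        model.fit(X)
    assert all(np.all(np.isfinite(p.data)) for p in model.params_)


def test_validation_trace_improves_on_smoke_run(small_corpus):
    X = small_corpus[0].patches
    model = ShallowVAE(dim_z1=60, lx_width=48, n_epochs=24, lr=2e-3,
                       random_state=1)
    model.fit(X[:1500], X_val=X[1500:1900])
    trace = np.asarray(model.history_["val_elbo"])
    k = len(trace) // 4
    assert trace[-k:].mean() > trace[:k].mean()


def test_reconstruction_zero_toy_and_baseline(tiny_shallow, small_corpus):
    zero_model = ShallowVAE(dim_z1=3, lx_width=2)
    zero_model._build(4, np.random.default_rng(0))
    for p in zero_model.params_:
        p.data[:] = 0.0
    _force_head(zero_model.z1_head_, 0.0, 1.0)
    np.testing.assert_allclose(zero_model.reconstruct(np.zeros((1, 4))), 0.0)
    # trained tiny model beats the mean-image baseline on held-out patches
    X = small_corpus[0].patches
    test = X[2000:2400]
    err_model = np.mean((tiny_shallow.reconstruct(test) - test) ** 2)
    err_base = np.mean((X[:2000].mean(axis=0) - test) ** 2)
    assert err_model < err_base
    # reconstruction is deterministic
    np.testing.assert_array_equal(tiny_shallow.reconstruct(test[:5]),
                                  tiny_shallow.reconstruct(test[:5]))


def test_train_determinism_same_seed(small_corpus):
    X = small_corpus[0].patches[:800]
    a = ShallowVAE(dim_z1=30, lx_width=24, n_epochs=4, random_state=7).fit(X)
    b = ShallowVAE(dim_z1=30, lx_width=24, n_epochs=4, random_state=7).fit(X)
    np.testing.assert_array_equal(a.A_.data, b.A_.data)


# ---------------------------------------------------------------------------
# active units


def test_two_means_recovers_planted_log_clusters():
    rng = np.random.default_rng(0)
    x = np.concatenate([rng.normal(-6, 0.3, 40), rng.normal(0, 0.3, 60)])
    mask, gap = _two_means_1d(x)
    assert gap > 2
    np.testing.assert_array_equal(mask, np.arange(100) >= 40)


def test_identify_active_units_excludes_silenced_units(tiny_shallow,
                                                       small_corpus):
    import copy

    model = copy.deepcopy(tiny_shallow)
    silenced = np.arange(0, model.dim_z1, 3)
    model.z1_head_.loc[0].data[:, silenced] = 0.0
    model.z1_head_.loc[1].data[silenced] = 0.0
    # collapsed units: constant zero location, posterior width = prior width
    model.z1_head_.raw_scale[0].data[:, silenced] = 0.0
    model.z1_head_.raw_scale[1].data[silenced] = _inv_softplus(1.0 - 1e-6)
    X = small_corpus[0].patches[:600]
    active, masks, disagreements = identify_active_units(model, X)
    assert not active[silenced].any()
    assert active[np.setdiff1d(np.arange(model.dim_z1), silenced)].mean() > 0.9


def test_identify_active_units_warns_on_unimodal_statistics(tiny_shallow,
                                                            small_corpus):
    X = small_corpus[0].patches[:400]
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        active, _, _ = identify_active_units(tiny_shallow, X, min_gap=1e9)
    assert active.all()
    assert any("unimodal" in str(w.message) for w in caught)


# ---------------------------------------------------------------------------
# checkpoint round trip


def test_model_save_load_round_trip(tmp_path, tiny_tdvae, small_corpus):
    path = tmp_path / "model.h5"
    save_model(tiny_tdvae, path)
    back = load_model(path)
    X = small_corpus[0].patches[:10]
    np.testing.assert_allclose(back.elbo(X, seed=0)[0],
                               tiny_tdvae.elbo(X, seed=0)[0])
    np.testing.assert_array_equal(back.A_.data, tiny_tdvae.A_.data)
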
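"""Corpus pipeline: cropping, histogram matching, truncated ZCA whitening,
and the synthetic image/texture generators."""

import numpy as np
import pytest
from scipy import stats as sps

from topdownvae import corpus
from topdownvae.corpus import (
    RawPatchSet,
    SyntheticCorpusConfig,
    ZCAWhitening,
    contrast_filter,
    crop_patches,
    generate_naturalistic_images,
    generate_texture_families,
    histogram_match_to_normal,
    retained_dimension,
)


# ---------------------------------------------------------------------------
# cropping


def test_single_valid_crop_yields_identical_patches():
    im = np.arange(1600, dtype=float).reshape(40, 40)
    ps = crop_patches([im], edge=40, n=3, seed=0)
    assert ps.n == 3
    for k in range(3):
        np.testing.assert_array_equal(ps.patches[k], im.ravel())


def test_crop_determinism_under_seed(rng):
    images = [rng.standard_normal((30, 30)) for _ in range(3)]
    a = crop_patches(images, 8, 50, seed=7)
    b = crop_patches(images, 8, 50, seed=7)
    np.testing.assert_array_equal(a.patches, b.patches)
    c = crop_patches(images, 8, 50, seed=8)
    assert not np.array_equal(a.patches, c.patches)


def test_crop_rejects_small_image_naming_index(rng):
    images = [rng.standard_normal((30, 30)), rng.standard_normal((5, 30))]
    with pytest.raises(ValueError, match="image 1"):
        crop_patches(images, 8, 10)


def test_paper_scale_crop_presets_documented():
    assert corpus.CROP_PRESETS == {40: 320_000, 50: 160_000, 20: 640_000}


# ---------------------------------------------------------------------------
# histogram matching


def test_pooled_match_is_quantile_function_evaluation():
    ps = RawPatchSet(np.array([[1.0], [2.0], [3.0], [4.0]]), edge=1)
    out = histogram_match_to_normal(ps)
    expected = sps.norm.ppf((np.arange(1, 5) - 0.5) / 4)
    np.testing.assert_allclose(np.sort(out.patches.ravel()), expected)


def test_pooled_match_zero_mean_unit_sd(rng):
    ps = RawPatchSet(rng.gamma(2.0, size=(50, 25)), edge=5)
    out = histogram_match_to_normal(ps)
    assert abs(out.patches.mean()) < 1e-6
    assert abs(out.patches.std() - 1.0) < 0.05


def test_match_monotone_and_affine_invariant(rng):
    vals = rng.gamma(2.0, size=(40, 16))
    a = histogram_match_to_normal(RawPatchSet(vals, edge=4)).patches
    b = histogram_match_to_normal(RawPatchSet(3.0 * vals - 7.0, edge=4)).patches
    np.testing.assert_allclose(a, b)
    flat_in, flat_out = vals.ravel(), a.ravel()
    order = np.argsort(flat_in)
    assert np.all(np.diff(flat_out[order]) >= 0)


def test_per_family_match_equalizes_first_order_statistics(rng):
    x = np.concatenate([rng.gamma(2.0, size=(30, 16)),
                        rng.normal(5, 3, size=(30, 16))])
    labels = np.repeat([1, 2], 30)
    out = histogram_match_to_normal(RawPatchSet(x, edge=4), labels=labels)
    fam1 = np.sort(out.patches[labels == 1].ravel())
    fam2 = np.sort(out.patches[labels == 2].ravel())
    ks = sps.ks_2samp(fam1, fam2).statistic
    assert ks < 0.01


def test_constant_group_rejected():
    with pytest.raises(ValueError, match="constant"):
        histogram_match_to_normal(RawPatchSet(np.ones((5, 4)), edge=2))


# ---------------------------------------------------------------------------
# whitening


@pytest.mark.parametrize("D,K", [(400, 314), (1600, 1256), (2500, 1963)])
def test_retention_rule_reproduces_effective_dimensions(D, K):
    assert retained_dimension(D) == K


def test_whitening_on_white_input_is_near_identity(rng):
    X = rng.standard_normal((4000, 36))
    wt = ZCAWhitening().fit(X)
    assert wt.retained_dim_ == retained_dimension(36)
    Y = wt.transform(X)
    C = np.cov(Y, rowvar=False)
    evals = np.sort(np.linalg.eigvalsh(C))[::-1]
    K = wt.retained_dim_
    np.testing.assert_allclose(evals[:K], 1.0, atol=0.15)
    np.testing.assert_allclose(evals[K:], 0.0, atol=1e-8)


def test_whitening_matrix_matches_closed_form_on_toy_covariance(rng):
    # D = 4 with known diagonal covariance: the whitening map must equal
    # U_K Lambda_K^(-1/2) U_K^T for the top-K eigenpairs
    var = np.array([4.0, 2.0, 1.0, 0.5])
    n = 200_000
    X = rng.standard_normal((n, 4)) * np.sqrt(var)
    wt = ZCAWhitening().fit(X)
    K = retained_dimension(4)
    assert K == 3
    C = np.cov(X - X.mean(0), rowvar=False)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1][:K]
    Uk, Lk = evecs[:, order], evals[order]
    W_oracle = Uk @ np.diag(1 / np.sqrt(Lk)) @ Uk.T
    W_fit = wt.pca_basis_ @ np.diag(1 / np.sqrt(wt.eigenvalues_)) \
        @ wt.pca_basis_.T
    np.testing.assert_allclose(W_fit, W_oracle, atol=1e-8)


def test_apply_then_invert_is_projection_oracle(rng):
    X = rng.standard_normal((2000, 25)) * np.linspace(3, 0.2, 25)
    wt = ZCAWhitening().fit(X)
    x = rng.standard_normal(25)
    back = wt.inverse_transform(wt.transform(x[None]))[0]
    P = wt.pca_basis_ @ wt.pca_basis_.T
    oracle = P @ (x - wt.mean_) + wt.mean_
    np.testing.assert_allclose(back, oracle, atol=1e-8)
    # fixed point for vectors already in the retained subspace
    v = wt.pca_basis_ @ rng.standard_normal(wt.retained_dim_) + wt.mean_
    np.testing.assert_allclose(wt.inverse_transform(wt.transform(v[None]))[0],
                               v, atol=1e-8)
    # discarded subspace maps to zero
    null = np.eye(25) - P
    w = null @ rng.standard_normal(25)
    np.testing.assert_allclose(wt.transform((w + wt.mean_)[None])[0], 0.0,
                               atol=1e-8)


def test_whitening_idempotence(small_corpus):
    white, wt = small_corpus
    X = white.patches[:50]
    again = wt.transform(wt.inverse_transform(X))
    np.testing.assert_allclose(again, X, atol=1e-8)


def test_whitening_rank_deficiency_reported():
    X = np.random.default_rng(0).standard_normal((500, 2)) @ \
        np.random.default_rng(1).standard_normal((2, 16))
    with pytest.raises(ValueError, match="rank"):
        ZCAWhitening().fit(X)


def test_whitening_dimension_mismatch():
    wt = ZCAWhitening().fit(np.random.default_rng(0).standard_normal((500, 16)))
    with pytest.raises(ValueError, match="mismatch"):
        wt.transform(np.zeros((1, 9)))


# ---------------------------------------------------------------------------
# synthetic naturalistic images


def _radial_log_slope(images):
    size = images[0].shape[0]
    P = np.mean([np.abs(np.fft.fft2(im)) ** 2 for im in images], axis=0)
    f = np.sqrt(np.add.outer(np.fft.fftfreq(size) ** 2,
                             np.fft.fftfreq(size) ** 2))
    bins = np.logspace(np.log10(2 / size), np.log10(0.4), 12)
    xs, ys = [], []
    for a, b in zip(bins[:-1], bins[1:]):
        sel = (f >= a) & (f < b)
        if sel.any():
            xs.append(np.log10(np.sqrt(a * b)))
            ys.append(np.log10(np.sqrt(P[sel].mean())))
    return np.polyfit(xs, ys, 1)[0]


@pytest.mark.parametrize("structure", ["gaussian", "oriented"])
def test_naturalistic_amplitude_slope(structure):
    cfg = SyntheticCorpusConfig(edge=16, n_images=20, image_size=128,
                                spectral_exponent=1.0, structure=structure,
                                rng_seed=0)
    slope = _radial_log_slope(generate_naturalistic_images(cfg))
    assert abs(slope - (-1.0)) < 0.1


def test_zero_exponent_gaussian_mode_is_iid_white_noise():
    cfg = SyntheticCorpusConfig(edge=16, n_images=6, image_size=64,
                                spectral_exponent=0.0, structure="gaussian",
                                rng_seed=0)
    ims = generate_naturalistic_images(cfg)
    pix = np.concatenate([im.ravel() for im in ims])
    # lag-1 autocorrelation in both directions is ~0 for iid pixels
    for ax in (0, 1):
        shifted = np.concatenate([np.roll(im, 1, axis=ax).ravel()
                                  for im in ims])
        r = np.corrcoef(pix, shifted)[0, 1]
        assert abs(r) < 0.03
    assert abs(sps.kurtosis(pix)) < 0.2


def test_naturalistic_seed_determinism():
    cfg = SyntheticCorpusConfig(edge=16, n_images=3, image_size=64, rng_seed=5)
    a = generate_naturalistic_images(cfg)
    b = generate_naturalistic_images(cfg)
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x, y)


def test_config_validation():
    with pytest.raises(ValueError):
        SyntheticCorpusConfig(n_images=0)
    with pytest.raises(ValueError):
        SyntheticCorpusConfig(spectral_exponent=3.0)
    with pytest.raises(ValueError):
        SyntheticCorpusConfig(n_families=1)


# ---------------------------------------------------------------------------
# texture families


@pytest.fixture(scope="module")
def texture_set():
    cfg = SyntheticCorpusConfig(edge=12, n_families=4, n_per_family=150,
                                rng_seed=3)
    return generate_texture_families(cfg)


def test_texture_balance_and_labels(texture_set):
    labels, counts = np.unique(texture_set.family_labels, return_counts=True)
    assert list(labels) == [1, 2, 3, 4]
    assert len(set(counts)) == 1


def test_texture_first_order_statistics_match_across_families():
    cfg = SyntheticCorpusConfig(edge=12, n_families=3, n_per_family=80,
                                rng_seed=3)
    ds = generate_texture_families(cfg, whiten=False)
    pools = [ds.patches[ds.family_labels == f].ravel() for f in (1, 2, 3)]
    for i in range(3):
        for j in range(i + 1, 3):
            a = np.random.default_rng(0).choice(pools[i], 10_000, replace=False)
            b = np.random.default_rng(1).choice(pools[j], 10_000, replace=False)
            assert sps.ks_2samp(a, b).statistic < 0.02


def test_texture_linear_pixel_decoding_at_chance(texture_set):
    from topdownvae.population import logistic_family_decoder

    rep = logistic_family_decoder(texture_set.patches,
                                  texture_set.family_labels, n_seeds=3)
    n_test = int(0.25 * len(texture_set.patches))
    se = np.sqrt(rep.chance_level * (1 - rep.chance_level) / n_test)
    assert abs(rep.accuracy_mean - rep.chance_level) < 3 * se + 0.02


def test_texture_quadratic_filter_statistics_decodable(texture_set):
    from topdownvae.corpus import oriented_filter_bank
    from topdownvae.population import logistic_family_decoder

    edge = texture_set.edge
    bank = oriented_filter_bank(edge)
    bf = np.fft.fft2(bank, axes=(-2, -1))
    imgs = texture_set.patches.reshape(-1, edge, edge)
    resp = np.fft.ifft2(np.fft.fft2(imgs)[:, None] * bf[None]).real
    feats = np.einsum("nkij,nlij->nkl", resp, resp).reshape(len(imgs), -1)
    rep = logistic_family_decoder(feats, texture_set.family_labels, n_seeds=3)
    assert rep.accuracy_mean > 2 * rep.chance_level


def test_identical_correlation_seeds_are_indistinguishable():
    from topdownvae.population import logistic_family_decoder

    cfg = SyntheticCorpusConfig(edge=12, n_families=2, n_per_family=150,
                                family_correlation_seeds=[11, 11], rng_seed=0)
    ds = generate_texture_families(cfg)
    rep = logistic_family_decoder(ds.patches, ds.family_labels, n_seeds=3)
    assert abs(rep.accuracy_mean - 0.5) < 0.12


def test_texture_determinism():
    cfg = SyntheticCorpusConfig(edge=12, n_families=3, n_per_family=20,
                                rng_seed=9)
    a = generate_texture_families(cfg, whiten=False)
    b = generate_texture_families(cfg, whiten=False)
    np.testing.assert_array_equal(a.patches, b.patches)


# ---------------------------------------------------------------------------
# contrast filter


def test_contrast_filter_strict_inequality_and_oracle(rng):
    sds = np.array([0.0, 0.1, 0.4, 0.41, 1.0, 0.39, 2.0, 0.4, 0.01, 0.7])
    X = rng.standard_normal((10, 25))
    X = (X - X.mean(axis=1, keepdims=True))
    X = X / X.std(axis=1, keepdims=True) * sds[:, None]
    X[0] = 0.0  # all-zero patch
    ps = RawPatchSet(X, edge=5)
    kept = contrast_filter(ps, threshold=0.4)
    oracle = X[X.std(axis=1) > 0.4]
    np.testing.assert_allclose(kept.patches, oracle)
    assert len(kept.patches) == 4  # 0.41, 1.0, 2.0, 0.7 survive; 0.4 excluded
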
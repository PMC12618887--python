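"""Shared fixtures: small synthetic corpora and quickly trained models.

Heavy, session-scoped fixtures (the desk-scale trained models used by the
end-to-end ordering tests) are built lazily so test sessions that do not
touch them stay fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from topdownvae import corpus, models


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_corpus():
    """Whitened 12x12 naturalistic patches plus their whitening transform."""
    cfg = corpus.SyntheticCorpusConfig(edge=12, n_images=30, image_size=96,
                                       rng_seed=1)
    images = corpus.generate_naturalistic_images(cfg)
    patches = corpus.crop_patches(images, 12, 2500, seed=1)
    matched = corpus.histogram_match_to_normal(patches)
    wt = corpus.fit_whitening(matched)
    return corpus.apply_whitening(matched, wt), wt


@pytest.fixture(scope="session")
def tiny_shallow(small_corpus):
    X = small_corpus[0].patches
    return models.ShallowVAE(dim_z1=120, lx_width=72, n_epochs=30, lr=2e-3,
                             random_state=0).fit(X)


@pytest.fixture(scope="session")
def tiny_tdvae(small_corpus):
    X = small_corpus[0].patches
    return models.TopDownVAE(dim_z1=120, dim_z2=8, lx_width=72, td_width=24,
                             cond_hidden=32, n_epochs=40, lr=2e-3,
                             beta_hold_epochs=10, beta_ramp_epochs=20,
                             random_state=0).fit(X)


# ---------------------------------------------------------------------------
# desk-scale bundle for the trained-model ordering suite


class _DeskBundle:
    """Trained desk-scale models, textures and derived artifacts, built once."""

    def __init__(self):
        from topdownvae import presets

        d = presets.DESK
        self.preset = d
        self.X, self.whitening = corpus.assemble_training_corpus(
            edge=d["edge"], n_naturalistic=d["n_naturalistic"],
            n_texture_families=d["n_train_texture_families"],
            n_per_family=d["n_per_train_family"], seed=1)
        cfg_t = corpus.SyntheticCorpusConfig(
            edge=d["edge"], n_families=d["n_texture_families"],
            n_per_family=d["n_per_family"], rng_seed=7)
        self.textures = corpus.generate_texture_families(
            cfg_t, whitening=self.whitening)
        self.tdvae = models.TopDownVAE(random_state=0, **d["tdvae"]).fit(self.X)
        self.shallow = models.ShallowVAE(random_state=0,
                                         **d["shallow"]).fit(self.X)
        self.active_z1, _, _ = models.identify_active_units(
            self.tdvae, self.X[:1000])
        self.active_z2, _, _ = models.identify_active_units(
            self.tdvae, self.X[:1000], layer="z2")


@pytest.fixture(scope="session")
def desk(request):
    return _DeskBundle()
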
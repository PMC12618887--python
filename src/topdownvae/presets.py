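"""Reference configurations.

`FULL_SCALE` documents the full-size study conditions (dimensions, corpus
sizes, schedules and the unit counts they produced); these are far beyond
desktop CPU budgets and are retained as documentation and for users with
the hardware to rerun them.  `DESK` is the reduced configuration this
package uses for its own end-to-end runs: a 16-pixel patch corpus with
proportionally scaled latent dimensions and training lengths, chosen so a
full train-and-analyze cycle completes in minutes on one CPU core while
preserving the qualitative structure of the full-scale models.
"""

from __future__ import annotations

FULL_SCALE = {
    "edges": (20, 40, 50),
    "crops_per_edge": {40: 320_000, 50: 160_000, 20: 640_000},
    "validation_patches": 64_000,
    "test_patches": 64_000,
    "dim_z1": 1800,
    "dim_z2": 250,
    "sigma_obs": 0.4,
    "batch_size": 128,
    "beta0": 0.1,
    "beta_hold_epochs": 1000,
    "beta_ramp_epochs": 1800,
    "retained_dims": {1600: 1256, 2500: 1963, 400: 314},
    "active_units_headline": {"z1": 1256, "z2": 6},
    "texture_train_patches": 600_000,
    "texture_test_patches": 60_000,
    "n_texture_families": 15,
    "sta_noise_images": 128_000,
    "stc_noise_images": 100_000_000,
    "snis_samples": {"means": 4_000, "correlations": 38_400_000},
    "central_localized_medium_counts": {"tdvae40": 40, "tdvae50": 57,
                                        "shallow50": 53},
    "illusory_eligible_counts": {"tdvae50": 9, "shallow50": 29, "tdvae40": 0},
    "illusory": {"pacman_radius": 9, "blur_sigma": 0.9, "shift_step": 0.125,
                 "n_trials": 500},
    "contour": {"bar_length": 11, "blur_sigma": 0.9, "contrast": 0.8,
                "n_trials": 30, "n_orientation_draws": 100},
    "noise_correlation_trials": 80,
    "signal_correlation_images_per_family": 80,
    "lr_schedules": {
        "shallow": [(3e-5, 12_000)],
        "tdvae_deep": [(1e-5, 205_700), (2e-5, 2_100), (3e-5, 5_700),
                       (5e-5, 900)],
        "tdvae_20px": [(1e-4, 6_000), (2e-4, 1_050), (3e-4, 300)],
    },
}

DESK = {
    "edge": 16,
    # training corpus: naturalistic crops pooled with patches from 48
    # randomly seeded texture families (disjoint from evaluation families)
    "n_naturalistic": 960,
    "n_train_texture_families": 48,
    "n_per_train_family": 80,
    # evaluation texture set
    "n_texture_families": 15,
    "n_per_family": 120,
    # top-down model: non-shared encoder pathway; beta annealed 0.1 -> 1,
    # then a temporary compression spike (beta = 3) pruning non-global
    # information from the Z2 code, and a recovery phase at beta = 1
    "tdvae": {
        "dim_z1": 288, "dim_z2": 24, "lx_width": 192, "td_width": 32,
        "cond_hidden": 48, "cond_depth": 2, "shared_encoder": False,
        "n_epochs": 660, "lr": 2e-3, "beta_hold_epochs": 60,
        "beta_ramp_epochs": 120,
        "beta_final_segments": [(1.0, 300), (3.0, 70), (1.0, 110)],
    },
    "shallow": {"dim_z1": 288, "lx_width": 192, "n_epochs": 60, "lr": 2e-3},
    # severed-feedback decoding is evaluated at reduced stimulus contrast,
    # where contextual-prior influence on the posterior is strongest
    "severed_contrast": 0.4,
    "snis_samples": {"means": 10_000, "correlations": 1_000_000},
    "sta_noise_images": 8_000,
}
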
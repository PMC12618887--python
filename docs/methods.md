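# Methods

## The model family

The package implements Markovian two-layer hierarchical latent-variable
generative models of grayscale image patches,

    p(image, Z1, Z2) = p(image | Z1) p(Z1 | Z2) p(Z2),

with a linear-Gaussian observation model `p(image | Z1) = N(A Z1 + b,
sigma_obs^2 I)` (`sigma_obs = 0.4` throughout), an overcomplete Z1 layer
under a sparse factorized Laplace prior, a standard-normal Z2 prior, and a
conditional prior `p(Z1 | Z2)` whose per-unit location and scale are
emitted by an MLP (depth 0 = linear integration, 1 = shallow, 2 = deep
conditional nonlinearity; depth 2 is the default).  Three variational
posteriors define the three estimators:

* **ShallowVAE** — no Z2; `q(Z1 | image)` against the fixed Laplace prior.
* **FeedForwardVAE** — `q(Z2 | Z1) q(Z1 | image)`; the objective carries the
  reconstruction term, the conditional-prior cross term, the entropy of
  `q(Z1 | image)` and the Z2 KL.
* **TopDownVAE** — `q(Z1 | image, Z2) q(Z2 | image)`: inference of Z1 is
  conditioned on the higher-level interpretation, implementing a
  stimulus-dependent contextual prior.  Four MLPs realize it: Z1-ff
  (image → shared layer L_x), Z2-ff (L_x, or its own image pathway in the
  non-shared variant), Z1-TD (Z2 → L_z) and Z1-INT (concat → posterior
  parameters).  All activations are softplus; scale heads output
  `softplus(raw) + 1e-6`.

`q(Z1 | ...)` is factorized Laplace by default (matching the sparse prior;
a Gaussian switch exists); `q(Z2 | image)` is factorized Gaussian.  The
fully-Laplace pathway admits closed-form Laplace–Laplace KL terms, so the
single-sample Monte Carlo ELBO only reparameterizes through the Z2 draw
and the reconstruction term.

Because no GPU autodiff framework is assumed, the package carries a small
reverse-mode automatic-differentiation engine over numpy arrays
(`topdownvae._autodiff`).  Gradient correctness is pinned by central
finite-difference tests at 1e-4 relative tolerance on 4-pixel toy models.
Training runs in float32 (roughly half the wall-clock of float64 on CPU);
all analysis-time computation is float64.

## Training

Adam, minibatch size 128, no weight decay.  Gradient clipping and update
skipping use thresholds relative to a running median of recent gradient
norms (factors 20 and 50), so they fire on a vanishing fraction of steps.
Hierarchical models anneal the weight `beta` on the final KL term: hold at
0.1, ramp linearly to 1, then (optionally) replay extra segments.  The
desk-scale schedule ends with a temporary compression spike (`beta = 3`
for 80 epochs, then back to 1): the spike prunes Z2 dimensions whose
information is cheap to discard (per-sample spatial detail) while the
texture-statistics code survives, sharpening the family representation —
the same compression manoeuvre used at full scale when the upper layer
retains non-global information.  The shallow model trains without
annealing.

## Preprocessing

Patches are randomly cropped, their pooled pixel histogram is rank-mapped
(average ties) onto standard-normal quantiles, and ZCA whitening restricted
to the top `K = floor(0.25 pi D)` principal components is applied in full
pixel coordinates (rank-K data in D dimensions).  For D = 400, 1600 and
2500 this retains 314, 1256 and 1963 components.  Texture datasets are
histogram-matched per family before whitening; by default a texture set is
whitened with the basis passed in (the natural-image basis), with
self-fitted whitening as the fallback.

## Synthetic data

Two generators make the package self-contained:

* **Naturalistic images** — sparse fields of randomly placed oriented
  odd-Gabor elements whose orientations follow a per-image two-component
  von Mises mixture (each image has its own anisotropic orientation
  profile, as real scenes do), spectrally reshaped to an exact isotropic
  `f^-alpha` amplitude spectrum (default `alpha = 1`).  A pure Gaussian
  phase mode exists; it reproduces the spectrum but carries no sparse
  structure, so no localized oriented code can emerge from it, and it is
  not used for training.
* **Texture families** — stationary Gaussian processes built by mixing an
  oriented filter bank with a family-specific diagonal-dominant mixing
  matrix: families differ in oriented-channel energies and cross-channel
  correlations while their first-order pixel statistics are equalized
  exactly by per-family histogram matching.  Consequently a linear pixel
  decoder operates at chance while decoders on squared-filter statistics
  succeed — the defining property of naturalistic texture families.

What the generators do *not* emulate: occlusion and phase alignment across
scales, luminance/contrast inhomogeneity, long-range contour statistics
beyond single elements, and the full Portilla–Simoncelli statistic set.
Passing tests therefore demonstrate the mechanisms (hierarchical texture
coding, top-down-induced correlations) on ensembles that carry those
statistics in controlled form, not performance on photographic data.

## Desk-scale study conditions

The trained-model analyses use a reduced configuration chosen once
(`presets.DESK`): 16-pixel patches (retained dimension 201), dim(Z1) = 288,
dim(Z2) = 24, non-shared encoder pathway, a 4,800-patch training corpus
pooling naturalistic crops with patches from 48 randomly seeded texture
families (disjoint from the 15 evaluation families), and a 660-epoch
schedule (anneal to beta = 1 by epoch 180, compression spike over epochs
480-550, recovery to 660).  The mixed corpus emulates, at this scale, a rich natural
ensemble in which stationary texture statistics are in-distribution; with
naturalistic patches alone the upper layer spends its capacity on coarse
per-patch spatial layout and texture-family information never becomes the
marginal-value code within desk-scale training lengths.  The non-shared
encoder matters for the same reason: with a shared first layer the Z2
pathway inherits layout-dominated features.  At full scale neither choice
is needed (the upper layer converges to a texture code regardless); both
are documented here as desk-scale accommodations and are configuration
switches, not code paths.

The severed-feedback decoding comparison is evaluated at reduced stimulus
contrast (0.4 in whitened-pixel units), where the contextual prior's
influence on the posterior is strongest.

## Sampling-hypothesis response simulation

Responses are samples from the variational posterior: one sample per
~20 ms (so a 500 ms trial holds 25 samples).  A window scheme `n_z2 x n_z1`
draws `n_z2` Z2 values per trial and `n_z1` conditional Z1 samples under
each, averaging all; "50 ms" is 1x3, "100 ms" 1x5, "400 ms" 1x20 / 2x10 /
4x5, with one Z2 sample shared within a window (slow top-down turnover).
Feedback interventions replace the Z2 source: posterior (intact / "late"),
prior with the image still reaching Z1 feed-forward ("early"), both layers
from the prior ("pre-stimulus"), or a clamped zero vector.  Correlation
analyses use the across-Z2 covariance of conditional locations
(Monte Carlo marginalization), which isolates top-down covariability and
excludes private variability; with Z2 clamped the off-diagonal covariance
is exactly zero.

SNIS validation draws joint samples from the variational posterior,
reweighs by `p(image, Z1, Z2) / q(Z1, Z2 | image)` in log space with
max-subtraction, discards the single largest-weight sample, and reports an
effective-sample-size diagnostic (warning below 10).  Desk presets are
10^4 samples for means and 10^6 for correlations.

## Characterization and analyses

STA/STC and orientation tuning use deterministic "mean-path" responses
(the conditional location at the Z2 posterior mean) — the low-variance
estimator of the mean response.  STC eigen-decomposes the
response-weighted stimulus covariance difference after projecting out the
mean and STA.  Receptive-field geometry: center of mass of the squared
field; envelope sigma from matching the moment of inertia of the absolute
field to a circular Gaussian (`I = 2 sigma^2`); dominant wave vector from
the FFT-power argmax over the non-DC half-plane with ties broken toward
lower frequency; the reported orientation is the stripe orientation
(perpendicular to the wave vector), the natural alignment axis for bar and
contour stimuli.

Vector stimuli render through one fixed pipeline: -1/+1 rasterization on a
16x supersampled grid, block-average downsampling, Gaussian blur (sigma in
final pixels), per-image Z-scoring (constant rasters map to zero with a
warning), and whitening with the natural-image basis.  Sub-pixel shifts are
realized exactly on the supersampled grid (0.125 px = 2 supersampled px).
The Kanizsa "Rotated" control rotates each pac-man in place by 90 degrees
(configurable); the "Line" stimulus adds a thin square outline to the
pac-man configuration.  The aligned illusory edge must fit the patch
(extended by 11.1%) for a unit to be eligible; whole-figure clipping is
allowed by default since only the aligned edge probes the unit.

Nested ANOVA uses classical balanced method-of-moments sums of squares
(components clipped at zero), percent shares, and the across-family /
across-sample ratio with a capped, flagged value when the sample share
vanishes; population summaries are geometric means of per-unit ratios.
Correlation-matrix dissimilarity is the mean absolute difference over the
off-diagonal upper triangle (the constant diagonal would dilute the
metric).  Statistical tests are Student t-tests in the one/two-sample,
paired/independent, one/two-sided variants, with pooled-SD effect sizes.

## Known limitations

* Desk-scale training does not reproduce full-scale statistics (ELBO
  values, active-unit counts, decoding levels); orderings and mechanisms
  are the supported surface.
* The top-down influence on Z1 posterior *locations* is weak in
  desk-scale models: the learned conditional predicts mainly per-unit
  scales.  Analyses that depend on location-level feedback (severed-
  feedback decoding gains, illusory-contour boosting magnitudes) have
  small effect sizes at this scale; in particular the intact-vs-severed
  decoding gap is significant under the standard desk conditions but is
  sensitive to the training seed, and can vanish or reverse for other
  seeds or schedules.
* The STC at desk scale uses planted units for validation; resolving
  second-order structure of trained units needs orders of magnitude more
  noise stimuli (10^8 at full scale).
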
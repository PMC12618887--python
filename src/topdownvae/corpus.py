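"""Image corpora: patch extraction, histogram matching, truncated ZCA
whitening, and synthetic stand-in generators.

The preprocessing pipeline mirrors the retinal-like front end used for
training the models: random square crops from large grayscale images, rank
mapping of the pooled pixel histogram onto a standard normal, and ZCA
whitening restricted to the leading ``floor(0.25*pi*D)`` principal
components, where ``D`` is the pixel count of a patch.

Two synthetic generators make the whole package testable without external
downloads:

* :func:`generate_naturalistic_images` draws images with an isotropic
  power-law amplitude spectrum and Gaussian phases, emulating the 1/f
  statistics of natural scenes.
* :func:`generate_texture_families` draws stationary Gaussian-process
  texture families whose first-order pixel statistics are matched across
  families while their pairwise oriented-filter co-activation statistics
  differ, the statistical structure that distinguishes naturalistic texture
  families from their phase-scrambled counterparts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "RawPatchSet",
    "TextureDataset",
    "SyntheticCorpusConfig",
    "ZCAWhitening",
    "retained_dimension",
    "crop_patches",
    "histogram_match_to_normal",
    "fit_whitening",
    "apply_whitening",
    "invert_whitening",
    "generate_naturalistic_images",
    "oriented_filter_bank",
    "generate_texture_families",
    "contrast_filter",
    "save_patchset",
    "load_patchset",
    "read_grayscale_image",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class RawPatchSet:
    """n x D matrix of flattened square patches of a common edge length."""

    patches: np.ndarray
    edge: int
    source_tag: str = ""

    def __post_init__(self):
        self.patches = np.asarray(self.patches, dtype=np.float64)
        if self.patches.ndim != 2:
            raise ValueError("patches must be a 2-D (n, D) array")
        n, D = self.patches.shape
        if n < 1:
            raise ValueError("need at least one patch")
        if D != self.edge**2:
            raise ValueError(f"patch dimension {D} != edge^2 = {self.edge ** 2}")
        if not np.all(np.isfinite(self.patches)):
            raise ValueError("patches contain non-finite values")

    @property
    def n(self) -> int:
        return self.patches.shape[0]

    @property
    def dim(self) -> int:
        return self.patches.shape[1]

    def images(self) -> np.ndarray:
        return self.patches.reshape(-1, self.edge, self.edge)


@dataclass
class TextureDataset:
    """Balanced set of texture patches with integer family labels 1..F."""

    patches: np.ndarray
    family_labels: np.ndarray
    edge: int
    provenance: str = "synthetic"
    whitening: "ZCAWhitening | None" = None

    def __post_init__(self):
        self.patches = np.asarray(self.patches, dtype=np.float64)
        self.family_labels = np.asarray(self.family_labels, dtype=int)
        if len(self.patches) != len(self.family_labels):
            raise ValueError("patches and labels differ in length")
        _, counts = np.unique(self.family_labels, return_counts=True)
        if len(set(counts)) != 1:
            raise ValueError("family label counts are not balanced")

    @property
    def n_families(self) -> int:
        return len(np.unique(self.family_labels))


@dataclass
class SyntheticCorpusConfig:
    """Parameters of the synthetic image and texture generators."""

    edge: int = 40
    n_images: int = 100
    image_size: int = 128
    spectral_exponent: float = 1.0
    structure: str = "oriented"  # 'oriented' (sparse elements) or 'gaussian'
    elements_per_image: int = 400
    n_families: int = 15
    n_per_family: int = 100
    family_correlation_seeds: list[int] | None = None
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_images <= 0:
            raise ValueError("n_images must be positive")
        if not 0.0 <= self.spectral_exponent <= 2.0:
            raise ValueError("spectral_exponent must lie in [0, 2]")
        if self.structure not in ("oriented", "gaussian"):
            raise ValueError("structure must be 'oriented' or 'gaussian'")
        if self.n_families < 2:
            raise ValueError("need at least two texture families")


# paper-scale corpus presets: edge -> number of random crops
CROP_PRESETS = {40: 320_000, 50: 160_000, 20: 640_000}


# ---------------------------------------------------------------------------
# patch extraction and first-order normalization


def crop_patches(images, edge: int, n: int, seed: int | np.random.Generator = 0,
                 source_tag: str = "") -> RawPatchSet:
    """Draw `n` random edge x edge crops uniformly over images and positions."""
    rng = np.random.default_rng(seed)
    images = [np.asarray(im, dtype=np.float64) for im in images]
    for i, im in enumerate(images):
        if im.ndim != 2 or im.shape[0] < edge or im.shape[1] < edge:
            raise ValueError(
                f"image {i} with shape {im.shape} is smaller than edge {edge}"
            )
    idx = rng.integers(0, len(images), size=n)
    out = np.empty((n, edge * edge))
    for k in range(n):
        im = images[idx[k]]
        r = rng.integers(0, im.shape[0] - edge + 1)
        c = rng.integers(0, im.shape[1] - edge + 1)
        out[k] = im[r:r + edge, c:c + edge].ravel()
    return RawPatchSet(out, edge=edge, source_tag=source_tag)


def histogram_match_to_normal(patches: RawPatchSet,
                              labels: np.ndarray | None = None) -> RawPatchSet:
    """Map pooled pixel values onto standard-normal quantiles by rank.

    With `labels`, matching is done separately within each label group
    (per texture family); otherwise the grand pooled histogram is matched.
    Ties receive average ranks, so the map is deterministic and
    permutation-invariant.
    """
    X = patches.patches.copy()
    if labels is None:
        groups = [np.arange(X.shape[0])]
    else:
        labels = np.asarray(labels)
        groups = [np.flatnonzero(labels == g) for g in np.unique(labels)]
    for rows in groups:
        vals = X[rows].ravel()
        if np.ptp(vals) == 0:
            raise ValueError("constant pixel group: quantile mapping undefined")
        ranks = stats.rankdata(vals, method="average")
        mapped = stats.norm.ppf((ranks - 0.5) / vals.size)
        X[rows] = mapped.reshape(X[rows].shape)
    return RawPatchSet(X, edge=patches.edge, source_tag=patches.source_tag)


def contrast_filter(patches: RawPatchSet, threshold: float = 0.4) -> RawPatchSet:
    """Keep patches whose pixel standard deviation strictly exceeds `threshold`."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    sds = patches.patches.std(axis=1)
    keep = sds > threshold
    if not np.any(keep):
        raise ValueError("no patch passes the contrast threshold")
    return RawPatchSet(patches.patches[keep], edge=patches.edge,
                       source_tag=patches.source_tag)


# ---------------------------------------------------------------------------
# whitening


def retained_dimension(D: int) -> int:
    """Number of retained PCA components: floor(0.25 * pi * D)."""
    return int(np.floor(0.25 * np.pi * D))


class ZCAWhitening(TransformerMixin, BaseEstimator):
    """Truncated ZCA whitening in full pixel coordinates.

    Fitting retains the ``floor(0.25*pi*D)`` largest-eigenvalue principal
    components of the patch covariance; transforming projects out the mean,
    scales the retained components to unit variance and rotates back to
    pixel space, so whitened data live in a rank-K subspace of the
    D-dimensional pixel space.
    """

    def __init__(self, eig_floor: float = 1e-10):
        self.eig_floor = eig_floor

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=np.float64)
        n, D = X.shape
        K = retained_dimension(D)
        if n < K:
            raise ValueError(f"need at least K={K} patches, got {n}")
        self.mean_ = X.mean(axis=0)
        C = np.cov(X - self.mean_, rowvar=False)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        rank = int(np.sum(evals > self.eig_floor * evals[0]))
        if rank < K:
            raise ValueError(
                f"covariance rank {rank} below required retained dimension {K}"
            )
        self.eigenvalues_ = evals[:K]
        self.pca_basis_ = evecs[:, :K]
        self.retained_dim_ = K
        self.n_features_in_ = D
        return self

    def _check(self, X):
        check_is_fitted(self, "pca_basis_")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"dimension mismatch: got {X.shape[1]}, expected {self.n_features_in_}"
            )
        return X

    def transform(self, X):
        X = self._check(X)
        proj = (X - self.mean_) @ self.pca_basis_
        return (proj / np.sqrt(self.eigenvalues_)) @ self.pca_basis_.T

    def inverse_transform(self, X):
        X = self._check(X)
        proj = X @ self.pca_basis_
        return (proj * np.sqrt(self.eigenvalues_)) @ self.pca_basis_.T + self.mean_


def fit_whitening(patches: RawPatchSet) -> ZCAWhitening:
    return ZCAWhitening().fit(patches.patches)


def apply_whitening(patches: RawPatchSet, transform: ZCAWhitening) -> RawPatchSet:
    return RawPatchSet(transform.transform(patches.patches), edge=patches.edge,
                       source_tag=patches.source_tag)


def invert_whitening(patches: RawPatchSet, transform: ZCAWhitening) -> RawPatchSet:
    return RawPatchSet(transform.inverse_transform(patches.patches),
                       edge=patches.edge, source_tag=patches.source_tag)


# ---------------------------------------------------------------------------
# synthetic naturalistic images


def _power_law_amplitude(size, exponent):
    fy = np.fft.fftfreq(size)[:, None]
    fx = np.fft.fftfreq(size)[None, :]
    f = np.sqrt(fx**2 + fy**2)
    with np.errstate(divide="ignore"):
        return np.where(f > 0, f ** (-exponent), 0.0)


def _oriented_element_field(rng, size, n_elements, orientation_kappa=4.0):
    """Sparse sum of randomly placed, oriented, scaled odd Gabor elements.

    This supplies the non-Gaussian, edge-like phase structure of natural
    scenes (oriented contours at sparse locations) that makes localized
    oriented filters the efficient sparse code of the ensemble.  Element
    orientations follow a per-image two-component von Mises mixture with
    random component means: like real scenes, each image has its own
    anisotropic orientation profile, a scene-level latent that a higher
    representational layer can capture.
    """
    im = np.zeros((size, size))
    mix_means = rng.uniform(0, np.pi, size=2)
    mix_w = rng.dirichlet((2.0, 2.0))
    # one shared coordinate grid; elements rendered in local windows
    for _ in range(n_elements):
        lam = np.exp(rng.uniform(np.log(4.0), np.log(size / 2.0)))
        sig = 0.5 * lam
        half = int(np.ceil(2.5 * sig))
        cx, cy = rng.integers(0, size, size=2)
        comp = rng.choice(2, p=mix_w)
        # von Mises on doubled angles gives an axial orientation distribution
        th = np.mod(mix_means[comp]
                    + 0.5 * rng.vonmises(0.0, orientation_kappa), np.pi)
        amp = rng.laplace(0.0, 1.0)
        xs = np.arange(-half, half + 1)
        X, Y = np.meshgrid(xs, xs, indexing="xy")
        u = X * np.cos(th) + Y * np.sin(th)
        g = amp * np.exp(-(X**2 + Y**2) / (2 * sig**2)) * np.sin(
            2 * np.pi * u / lam)
        rows = (cy + xs) % size
        cols = (cx + xs) % size
        im[np.ix_(rows, cols)] += g
    return im


def generate_naturalistic_images(config: SyntheticCorpusConfig) -> list[np.ndarray]:
    """Synthetic images with amplitude spectrum ~ f^(-spectral_exponent).

    Two phase-structure modes:

    * ``'gaussian'`` -- random (Gaussian) phases: a stationary Gaussian
      process with the requested spectrum; exponent 0 gives i.i.d. white
      noise.
    * ``'oriented'`` (default) -- phases come from a sparse field of
      randomly placed oriented elements, then the radial amplitude
      spectrum is reshaped to the exact power law.  This retains the
      sparse, edge-like higher-order structure of natural scenes that the
      Gaussian mode lacks.
    """
    rng = np.random.default_rng(config.rng_seed)
    size = config.image_size
    amp = _power_law_amplitude(size, config.spectral_exponent)
    images = []
    for _ in range(config.n_images):
        if config.structure == "gaussian":
            white = rng.standard_normal((size, size))
            im = np.fft.ifft2(np.fft.fft2(white) * amp).real
        else:
            base = _oriented_element_field(rng, size, config.elements_per_image)
            F = np.fft.fft2(base)
            mag = np.abs(F)
            phase = np.where(mag > 0, F / np.where(mag > 0, mag, 1.0), 1.0)
            im = np.fft.ifft2(phase * amp).real
        im /= im.std() + 1e-12
        images.append(im)
    return images


# ---------------------------------------------------------------------------
# synthetic texture families


def oriented_filter_bank(edge: int, n_orientations: int = 4,
                         wavelength_frac: float = 0.25,
                         sigma_frac: float = 0.15) -> np.ndarray:
    """Gabor-like oriented kernels on the patch grid (for texture synthesis)."""
    xs = np.arange(edge) - edge / 2.0
    X, Y = np.meshgrid(xs, xs, indexing="xy")
    lam = wavelength_frac * edge
    sig = sigma_frac * edge
    bank = []
    for k in range(n_orientations):
        theta = np.pi * k / n_orientations
        u = X * np.cos(theta) + Y * np.sin(theta)
        g = np.exp(-(X**2 + Y**2) / (2 * sig**2)) * np.cos(2 * np.pi * u / lam)
        g -= g.mean()
        g /= np.sqrt(np.sum(g**2))
        bank.append(g)
    return np.asarray(bank)


def _family_mixing(seed: int, n_chan: int) -> np.ndarray:
    """Family-specific channel mixing; M M^T is the co-activation signature.

    Diagonal-dominant mixing: each family has a strongly anisotropic
    oriented-channel energy profile (weights spanning nearly an order of
    magnitude) plus a mild random rotation that introduces family-specific
    cross-channel correlations.
    """
    rng = np.random.default_rng(seed)
    w = rng.permutation(np.geomspace(1.0, 8.0, n_chan))
    Q = np.linalg.qr(np.eye(n_chan)
                     + 0.3 * rng.standard_normal((n_chan, n_chan)))[0]
    return Q * w


def generate_texture_families(config: SyntheticCorpusConfig,
                              whitening: ZCAWhitening | None = None,
                              whiten: bool = True,
                              n_orientations: int = 4) -> TextureDataset:
    """Stationary Gaussian textures with family-specific filter correlations.

    Each family mixes a fixed oriented filter bank with a family-specific
    channel-mixing matrix, then convolves the mixed channels with
    independent white-noise fields (circularly, via the FFT).  Families are
    zero-mean Gaussian processes, so their class means coincide and a linear
    pixel decoder operates at chance; their second-order filter
    co-activation statistics differ and support quadratic decoding.  After
    generation, each family's pooled pixel histogram is matched to the
    standard normal, equalizing first-order statistics exactly in rank.
    """
    rng = np.random.default_rng(config.rng_seed)
    F, P, edge = config.n_families, config.n_per_family, config.edge
    seeds = config.family_correlation_seeds
    if seeds is None:
        seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=F)]
    if len(seeds) != F:
        raise ValueError("family_correlation_seeds length must equal n_families")
    bank = oriented_filter_bank(edge, n_orientations=n_orientations)
    bank_f = np.fft.fft2(bank, axes=(-2, -1))
    n_chan = len(bank)
    patches = np.empty((F * P, edge * edge))
    labels = np.empty(F * P, dtype=int)
    row = 0
    for fam in range(F):
        M = _family_mixing(seeds[fam], n_chan)
        if np.linalg.matrix_rank(M) < n_chan:
            raise ValueError(f"degenerate family covariance for family {fam + 1}")
        noise = rng.standard_normal((P, n_chan, edge, edge))
        noise_f = np.fft.fft2(noise, axes=(-2, -1))
        # mix channels, convolve with bank, sum channels
        mixed = np.einsum("kl,plij->pkij", M, noise_f)
        imgs = np.fft.ifft2((mixed * bank_f[None]).sum(axis=1)).real
        patches[row:row + P] = imgs.reshape(P, -1)
        labels[row:row + P] = fam + 1
        row += P
    raw = RawPatchSet(patches, edge=edge, source_tag="synthetic-textures")
    matched = histogram_match_to_normal(raw, labels=labels)
    transform = None
    X = matched.patches
    if whiten:
        transform = whitening if whitening is not None else ZCAWhitening().fit(X)
        X = transform.transform(X)
    return TextureDataset(X, labels, edge=edge, provenance="synthetic",
                          whitening=transform)


def assemble_training_corpus(edge: int = 16, n_naturalistic: int = 1200,
                             n_texture_families: int = 48,
                             n_per_family: int = 100, image_size: int = 128,
                             n_images: int = 30, seed: int = 1):
    """Mixed whitened training corpus: naturalistic crops + texture patches.

    Emulates, at desk scale, a rich natural-image ensemble in which both
    sparse oriented scene structure and stationary texture statistics are
    in-distribution: random crops of synthetic naturalistic images are
    pooled with patches from `n_texture_families` randomly seeded texture
    families (disjoint from any evaluation families), the pooled histogram
    is matched to the standard normal per source, and one truncated-ZCA
    whitening transform is fitted on the pooled set.

    Returns (X, whitening): the whitened patch matrix (shuffled) and the
    fitted transform.
    """
    cfg = SyntheticCorpusConfig(edge=edge, n_images=n_images,
                                image_size=image_size, rng_seed=seed)
    images = generate_naturalistic_images(cfg)
    nat = histogram_match_to_normal(
        crop_patches(images, edge, n_naturalistic, seed=seed))
    cfg_tex = SyntheticCorpusConfig(edge=edge, n_families=n_texture_families,
                                    n_per_family=n_per_family,
                                    rng_seed=seed + 10_000)
    tex = generate_texture_families(cfg_tex, whiten=False)
    pooled = np.vstack([nat.patches, tex.patches])
    wt = ZCAWhitening().fit(pooled)
    X = wt.transform(pooled)
    np.random.default_rng(seed).shuffle(X)
    return X, wt


# ---------------------------------------------------------------------------
# I/O


def save_patchset(path, patches: np.ndarray, edge: int, labels=None,
                  seed=None, provenance: str = ""):
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("patches", data=patches)
        if labels is not None:
            f.create_dataset("labels", data=np.asarray(labels))
        f.attrs["edge"] = edge
        f.attrs["provenance"] = provenance
        if seed is not None:
            f.attrs["seed"] = seed


def load_patchset(path):
    import h5py

    with h5py.File(path, "r") as f:
        patches = f["patches"][()]
        labels = f["labels"][()] if "labels" in f else None
        meta = dict(f.attrs)
    return patches, labels, meta


def read_grayscale_image(path, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a grayscale image; `.iml` rasters need an explicit `shape`.

    The `.iml` convention is a headerless big-endian unsigned 16-bit raster
    (rows x cols given by `shape`, commonly 1024 x 1536).  Other formats are
    read through Pillow.
    """
    path = str(path)
    if path.endswith(".iml"):
        if shape is None:
            raise ValueError(".iml rasters need shape=(rows, cols)")
        data = np.fromfile(path, dtype=">u2")
        if data.size != shape[0] * shape[1]:
            raise ValueError(f"raster size {data.size} != {shape[0]}x{shape[1]}")
        return data.reshape(shape).astype(np.float64)
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im.convert("F"), dtype=np.float64)
    return arr
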
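"""Probe stimulus generation under a single rendering contract.

Vector figures (disks, pac-men, bars) are defined in continuous final-pixel
coordinates and rendered by the fixed pipeline: rasterize on a 16x
supersampled grid in black (-1) / white (+1), block-average downsample,
Gaussian blur (sigma in final pixels), per-image Z-score, and optional
whitening with a natural-image basis.  Sub-pixel placement is realized on
the supersampled grid (a 0.125 px step is exactly 2 supersampled pixels),
avoiding interpolation ambiguity.

Scrambles: :func:`phase_scramble` randomizes Fourier phases with Hermitian
symmetry (amplitude spectrum preserved exactly); :func:`filter_scramble`
permutes a linear model's latent activations within active/inactive sets
before decoding, destroying filter co-activation structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .corpus import RawPatchSet, ZCAWhitening, histogram_match_to_normal

__all__ = [
    "RenderSpec",
    "Disk",
    "Pacman",
    "Bar",
    "KanizsaSweep",
    "ContourStimulusSet",
    "phase_scramble",
    "filter_scramble",
    "white_noise_stimuli",
    "grating",
    "render_figure",
    "kanizsa_sweep",
    "contour_completion_set",
]


# ---------------------------------------------------------------------------
# scrambles and elementary stimuli


def phase_scramble(image, seed=0):
    """Randomize Fourier phases, preserving the amplitude spectrum.

    The random phase field is Hermitian by construction (phases of the FFT
    of a real white-noise field), so the output is exactly real; the DC
    ratio is forced to +1 so the mean intensity is preserved.
    """
    image = np.asarray(image, dtype=np.float64)
    rng = np.random.default_rng(seed)
    F = np.fft.fft2(image)
    R = np.fft.fft2(rng.standard_normal(image.shape))
    mag = np.abs(R)
    ratio = np.where(mag > 0, R / np.where(mag > 0, mag, 1.0), 1.0)
    ratio.flat[0] = 1.0  # preserve the DC component
    return np.fft.ifft2(F * ratio).real


def filter_scramble(image, shallow_model, active_mask, seed=0,
                    whitening: ZCAWhitening | None = None,
                    permutation=None, postprocess: bool = True):
    """Permute linear-model latent activations, then decode the mean image.

    Activations are permuted separately within the active and within the
    inactive unit sets, so overall activation statistics per set are kept.
    With `postprocess`, the decoded image is histogram matched and whitened
    like any other stimulus.
    """
    image = np.asarray(image, dtype=np.float64)
    flat = image.ravel()[None]
    if flat.shape[1] != shallow_model.n_features_in_:
        raise ValueError("image dimension does not match the model")
    z = shallow_model.posterior_mean_z1(flat, seed=0)[0]
    active_mask = np.asarray(active_mask, dtype=bool)
    rng = np.random.default_rng(seed)
    if permutation is None:
        permutation = np.arange(z.size)
        for mask in (active_mask, ~active_mask):
            idx = np.flatnonzero(mask)
            permutation[idx] = idx[rng.permutation(idx.size)]
    out = shallow_model.decode(z[permutation])[0]
    edge = int(np.sqrt(out.size))
    if not postprocess:
        return out.reshape(edge, edge)
    matched = histogram_match_to_normal(
        RawPatchSet(out[None], edge=edge, source_tag="filter-scramble"))
    pix = matched.patches
    if whitening is not None:
        pix = whitening.transform(pix)
    return pix[0].reshape(edge, edge)


def white_noise_stimuli(n, edge, mean=0.0, sd=1.0, seed=0) -> RawPatchSet:
    """IID Gaussian pixel noise; defaults match a zero-mean unit-sd corpus."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(seed)
    return RawPatchSet(rng.normal(mean, sd, size=(n, edge * edge)), edge=edge,
                       source_tag="white-noise")


def grating(orientation, phase, wavelength, contrast, edge):
    """Sinusoidal grating; contrast is the pixel standard deviation."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    xs = np.arange(edge, dtype=np.float64)
    X, Y = np.meshgrid(xs, xs, indexing="xy")
    u = X * np.cos(orientation) + Y * np.sin(orientation)
    g = np.sin(2 * np.pi * u / wavelength + phase)
    sd = g.std()
    if sd == 0:
        return np.zeros_like(g)
    return g * (contrast / sd)


# ---------------------------------------------------------------------------
# vector figures and rendering


@dataclass(frozen=True)
class RenderSpec:
    """Rendering contract for vector figures."""

    edge: int = 50
    supersample_factor: int = 16
    blur_sigma: float = 0.9
    whiten_with: ZCAWhitening | None = None

    def __post_init__(self):
        if self.supersample_factor < 1:
            raise ValueError("supersample_factor must be >= 1")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")


@dataclass(frozen=True)
class Disk:
    cx: float
    cy: float
    r: float

    def contains(self, X, Y):
        return (X - self.cx) ** 2 + (Y - self.cy) ** 2 <= self.r**2

    def bbox(self):
        return (self.cx - self.r, self.cy - self.r,
                self.cx + self.r, self.cy + self.r)


@dataclass(frozen=True)
class Pacman:
    """Disk with a 90-degree mouth sector removed around `mouth_angle`."""

    cx: float
    cy: float
    r: float
    mouth_angle: float  # radians; direction the mouth opens toward
    mouth_halfwidth: float = np.pi / 4

    def contains(self, X, Y):
        dx, dy = X - self.cx, Y - self.cy
        inside = dx**2 + dy**2 <= self.r**2
        ang = np.arctan2(dy, dx)
        diff = np.angle(np.exp(1j * (ang - self.mouth_angle)))
        return inside & ~(np.abs(diff) <= self.mouth_halfwidth)

    def bbox(self):
        return (self.cx - self.r, self.cy - self.r,
                self.cx + self.r, self.cy + self.r)


@dataclass(frozen=True)
class Bar:
    """Rotated rectangle of given length/width centered at (cx, cy)."""

    cx: float
    cy: float
    length: float
    width: float
    angle: float  # radians, long-axis direction

    def contains(self, X, Y):
        dx, dy = X - self.cx, Y - self.cy
        u = dx * np.cos(self.angle) + dy * np.sin(self.angle)
        v = -dx * np.sin(self.angle) + dy * np.cos(self.angle)
        return (np.abs(u) <= self.length / 2) & (np.abs(v) <= self.width / 2)

    def bbox(self):
        c, s = abs(np.cos(self.angle)), abs(np.sin(self.angle))
        hx = (self.length * c + self.width * s) / 2
        hy = (self.length * s + self.width * c) / 2
        return (self.cx - hx, self.cy - hy, self.cx + hx, self.cy + hy)


def figure_fits(primitives, edge) -> bool:
    for p in primitives:
        x0, y0, x1, y1 = p.bbox()
        if x0 < 0 or y0 < 0 or x1 > edge or y1 > edge:
            return False
    return True


def rasterize(primitives, spec: RenderSpec) -> np.ndarray:
    """Supersampled -1/+1 raster of the union of primitives."""
    ss, edge = spec.supersample_factor, spec.edge
    n = edge * ss
    coords = (np.arange(n) + 0.5) / ss
    X, Y = np.meshgrid(coords, coords, indexing="xy")
    mask = np.zeros((n, n), dtype=bool)
    for p in primitives:
        mask |= p.contains(X, Y)
    return np.where(mask, 1.0, -1.0)


def render_figure(primitives, spec: RenderSpec, check_fit: bool = True):
    """Rasterize, downsample, blur, Z-score, and optionally whiten.

    A constant raster (all background) has a degenerate Z-score and maps to
    the zero image with a warning, keeping stimulus batches rectangular.
    """
    if check_fit:
        for i, p in enumerate(primitives):
            x0, y0, x1, y1 = p.bbox()
            if x0 < 0 or y0 < 0 or x1 > spec.edge or y1 > spec.edge:
                raise ValueError(f"primitive {i} ({p}) exceeds the canvas")
    ss = spec.supersample_factor
    hi = rasterize(primitives, spec)
    lo = hi.reshape(spec.edge, ss, spec.edge, ss).mean(axis=(1, 3))
    if spec.blur_sigma > 0:
        lo = gaussian_filter(lo, spec.blur_sigma)
    sd = lo.std()
    if sd == 0:
        warnings.warn("degenerate Z-score (constant raster): returning zeros")
        return np.zeros_like(lo)
    lo = (lo - lo.mean()) / sd
    if spec.whiten_with is not None:
        lo = spec.whiten_with.transform(lo.ravel()[None])[0].reshape(lo.shape)
    return lo


# ---------------------------------------------------------------------------
# Kanizsa sweeps


@dataclass
class KanizsaSweep:
    """Line / Illusory / Rotated stimulus stacks over a shift grid."""

    shifts: np.ndarray
    stimuli: dict  # type -> (n_shifts, edge, edge)
    geometry: dict
    eligible: bool
    orientation_variant: str = "upright"


def _kanizsa_primitives(stimulus_type, corners, center, radius, line_width,
                        rotated_angle):
    prims = []
    if stimulus_type == "Line":
        for c in corners:
            ang = np.arctan2(center[1] - c[1], center[0] - c[0])
            prims.append(Pacman(c[0], c[1], radius, ang))
        for a, bpt in zip(corners, np.roll(corners, -1, axis=0)):
            mid = (a + bpt) / 2
            seg = bpt - a
            L = np.linalg.norm(seg)
            prims.append(Bar(mid[0], mid[1], L, line_width,
                             np.arctan2(seg[1], seg[0])))
    elif stimulus_type == "Illusory":
        for c in corners:
            ang = np.arctan2(center[1] - c[1], center[0] - c[0])
            prims.append(Pacman(c[0], c[1], radius, ang))
    elif stimulus_type == "Rotated":
        for c in corners:
            ang = np.arctan2(center[1] - c[1], center[0] - c[0])
            prims.append(Pacman(c[0], c[1], radius,
                                ang + np.deg2rad(rotated_angle)))
    else:
        raise ValueError(f"unknown stimulus type {stimulus_type!r}")
    return prims


def _kanizsa_corners(base, e, nvec, square_side, shift):
    """Corners (aligned edge first) and square center at a given shift."""
    edge_mid = base + shift * nvec
    half = square_side / 2
    sq_center = edge_mid + half * nvec
    corners = np.array([
        edge_mid - half * e,
        edge_mid + half * e,
        sq_center + half * e + half * nvec,
        sq_center - half * e + half * nvec,
    ])
    return corners, sq_center


def kanizsa_figure_masks(sweep: "KanizsaSweep", spec: RenderSpec,
                         shift: float = 0.0):
    """(illusory_mask, line_mask): final-resolution figure-pixel masks.

    Masks mark pixels with any figure coverage in the unblurred
    downsampled raster, used by the field/stimulus overlap eligibility
    criterion.
    """
    g = sweep.geometry
    corners, center = _kanizsa_corners(g["aligned_center"], g["edge_direction"],
                                       g["normal_direction"], g["square_side"],
                                       shift)
    masks = []
    for t in ("Illusory", "Line"):
        prims = _kanizsa_primitives(t, corners, center, g["pacman_radius"],
                                    g.get("line_width", 1.0), 90.0)
        hi = rasterize(prims, spec)
        ss = spec.supersample_factor
        lo = hi.reshape(spec.edge, ss, spec.edge, ss).mean(axis=(1, 3))
        masks.append(lo > -1.0 + 1e-9)
    return tuple(masks)


def kanizsa_sweep(unit_geometry, spec: RenderSpec, step: float = 0.125,
                  n_steps: int = 16, pacman_radius: float = 9.0,
                  square_side: float | None = None, line_width: float = 1.0,
                  rotated_angle: float = 90.0,
                  orientation_variant: str = "upright",
                  require_full_fit: bool = False) -> KanizsaSweep:
    """Line/Illusory/Rotated sweep aligned to one unit's receptive field.

    One illusory edge lies along the unit's preferred orientation through
    its receptive-field center; shifts displace the whole figure
    perpendicular to that edge in steps realized exactly on the
    supersampled grid.  Rendering clips primitives at the canvas; the
    sweep is marked ineligible (never raises) when the two pac-men of the
    aligned edge do not fully fit the patch at every shift, or, with
    `require_full_fit`, when any primitive clips.
    """
    if square_side is None:
        square_side = 3.0 * pacman_radius
    cx, cy = unit_geometry.center_of_mass[1], unit_geometry.center_of_mass[0]
    theta = unit_geometry.orientation
    e = np.array([np.cos(theta), np.sin(theta)])  # edge direction
    nvec = np.array([-np.sin(theta), np.cos(theta)])
    if orientation_variant == "upside_down":
        nvec = -nvec
    ss = spec.supersample_factor
    # realize the requested step on the supersampled grid
    step_ss = max(1, round(step * ss)) / ss
    shifts = (np.arange(-n_steps, n_steps + 1)) * step_ss
    base = np.array([cx, cy])
    types = ("Line", "Illusory", "Rotated")
    stacks = {t: [] for t in types}
    eligible = True
    geometry = {
        "square_side": square_side,
        "pacman_radius": pacman_radius,
        "edge_direction": e,
        "normal_direction": nvec,
        "aligned_center": base.copy(),
        "theta": theta,
        "line_width": line_width,
    }
    for s in shifts:
        corners, sq_center = _kanizsa_corners(base, e, nvec, square_side, s)
        aligned = [Disk(c[0], c[1], pacman_radius) for c in corners[:2]]
        if not figure_fits(aligned, spec.edge):
            eligible = False
        for t in types:
            prims = _kanizsa_primitives(t, corners, sq_center, pacman_radius,
                                        line_width, rotated_angle)
            if require_full_fit and not figure_fits(prims, spec.edge):
                eligible = False
            stacks[t].append(render_figure(prims, spec, check_fit=False))
    return KanizsaSweep(
        shifts=shifts,
        stimuli={t: np.asarray(v) for t, v in stacks.items()},
        geometry=geometry,
        eligible=eligible,
        orientation_variant=orientation_variant,
    )


# ---------------------------------------------------------------------------
# contour completion lattices


@dataclass
class ContourStimulusSet:
    condition: str
    stimuli: np.ndarray  # (n_draws, edge, edge)
    geometry: dict
    seed: int


def contour_completion_set(unit_geometry, spec: RenderSpec,
                           condition: str = "random_segments",
                           bar_length: float = 11.0, bar_width: float = 1.0,
                           lattice_constant: float | None = None,
                           contrast: float = 0.8, n_draws: int = 100,
                           seed: int = 0) -> ContourStimulusSet:
    """Bar-lattice contour stimuli aligned to one unit.

    The central bar sits on the unit's receptive-field center at its
    preferred orientation.  In `random_segments`, every other bar takes an
    independent uniform orientation on [0, pi); in `three_parallel`, the
    two lattice neighbors along the contour axis are collinear with the
    central bar and the rest are random.  The lattice constant defaults to
    1.5x the bar length reduced by 10%, and stimulus contrast (sd of the
    whitened pixels) is scaled to `contrast`.
    """
    if condition not in ("random_segments", "three_parallel"):
        raise ValueError(f"unknown condition {condition!r}")
    if lattice_constant is None:
        lattice_constant = 1.5 * bar_length * 0.9
    rng = np.random.default_rng(seed)
    cx, cy = unit_geometry.center_of_mass[1], unit_geometry.center_of_mass[0]
    theta = unit_geometry.orientation
    e = np.array([np.cos(theta), np.sin(theta)])
    nvec = np.array([-np.sin(theta), np.cos(theta)])
    half_extent = bar_length / 2 + bar_width
    n_side = int(np.floor((spec.edge / lattice_constant) / 2)) + 1
    centers, tags = [], []
    for i in range(-n_side, n_side + 1):
        for j in range(-n_side, n_side + 1):
            c = np.array([cx, cy]) + i * lattice_constant * e \
                + j * lattice_constant * nvec
            if (c[0] - half_extent < 0 or c[1] - half_extent < 0
                    or c[0] + half_extent > spec.edge
                    or c[1] + half_extent > spec.edge):
                continue
            centers.append(c)
            tags.append((i, j))
    stimuli = []
    drawn_orientations = []
    for _ in range(n_draws):
        prims = []
        draw_angles = []
        for c, (i, j) in zip(centers, tags):
            if i == 0 and j == 0:
                ang = theta
            elif condition == "three_parallel" and j == 0 and abs(i) == 1:
                ang = theta
            else:
                ang = rng.uniform(0, np.pi)
                draw_angles.append(ang)
            prims.append(Bar(c[0], c[1], bar_length, bar_width, ang))
        im = render_figure(prims, spec, check_fit=False)
        sd = im.std()
        if sd > 0:
            im = im * (contrast / sd)
        stimuli.append(im)
        drawn_orientations.append(draw_angles)
    return ContourStimulusSet(
        condition=condition,
        stimuli=np.asarray(stimuli),
        geometry={"bar_length": bar_length, "bar_width": bar_width,
                  "lattice_constant": lattice_constant,
                  "n_bars": len(centers), "theta": theta,
                  "center": (cx, cy),
                  "random_orientations": drawn_orientations},
        seed=seed,
    )
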
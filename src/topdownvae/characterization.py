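"""Single-unit characterization: receptive fields, projective fields,
orientation tuning, receptive-field geometry and unit selection.

Responses used for reverse correlation and tuning are deterministic
"mean-path" posterior means: the Z1 conditional location evaluated at the
Z2 posterior mean (for hierarchical models) or the Z1 posterior location
(single-layer models).  This is the low-variance estimator of the mean
response and keeps reverse correlation at large stimulus counts cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReceptiveFieldSummary",
    "TuningCurve",
    "mean_path_responses",
    "sta",
    "stc",
    "projective_field",
    "orientation_tuning",
    "rf_geometry",
    "select_central_localized_medium",
    "illusory_overlap_ratio",
    "illusory_fit_criterion",
    "peak_shift_spread",
    "select_illusory_eligible",
]


@dataclass
class ReceptiveFieldSummary:
    """Field image with derived geometry.

    `orientation` is the orientation of the field's elongated structure
    (perpendicular to the dominant wave vector), i.e. the direction along
    which a bar or edge stimulus is best aligned with the unit.
    """

    field: np.ndarray
    center_of_mass: tuple  # (row, col), continuous
    envelope_sigma: float
    dominant_wave_vector: np.ndarray  # cycles / pixel
    dominant_wavelength: float
    orientation: float  # radians, stripe orientation in [0, pi)


@dataclass
class TuningCurve:
    orientations: np.ndarray
    response_amplitude: np.ndarray  # max - min over phase

    def __post_init__(self):
        if np.any(self.response_amplitude < -1e-12):
            raise ValueError("amplitudes must be non-negative")

    @property
    def preferred_orientation(self):
        return self.orientations[int(np.argmax(self.response_amplitude))]


# ---------------------------------------------------------------------------
# responses


def mean_path_responses(model, X, layer: str = "z1") -> np.ndarray:
    """Deterministic posterior-mean responses (Z2 fixed at its mean)."""
    from ._autodiff import Tensor

    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if layer == "z2":
        return model.encode_z2(X)[0]
    if not model.hierarchical:
        return model.encode_z1(X)[0]
    mu2, _ = model.encode_z2(X)
    lx = model.encode_lx(X)
    loc, _ = model._q_z1(Tensor(lx), Tensor(mu2))
    return loc.data


# ---------------------------------------------------------------------------
# reverse correlation


def sta(model, noise_images, units=None, layer: str = "z1",
        batch_size: int = 4096, rectify: bool = False) -> np.ndarray:
    """Spike-triggered averages from posterior-mean responses.

    Returns (n_units, edge, edge) response-weighted mean stimuli,
    normalized per unit by the response variance so a purely linear unit's
    STA recovers its filter under white noise.  With `rectify`, absolute
    responses weight the average (useful for sign-symmetric units).
    """
    S = np.asarray(getattr(noise_images, "patches", noise_images),
                   dtype=np.float64)
    n, D = S.shape
    edge = int(np.sqrt(D))
    # accumulate sums in one pass over batches
    sum_r = sum_r2 = None
    sum_rs = None
    sum_s = np.zeros(D)
    for start in range(0, n, batch_size):
        sb = S[start:start + batch_size]
        r = mean_path_responses(model, sb, layer=layer)
        if units is not None:
            r = r[:, np.asarray(units)]
        if rectify:
            r = np.abs(r)
        if sum_r is None:
            sum_r = np.zeros(r.shape[1])
            sum_r2 = np.zeros(r.shape[1])
            sum_rs = np.zeros((r.shape[1], D))
        sum_r += r.sum(axis=0)
        sum_r2 += (r**2).sum(axis=0)
        sum_rs += r.T @ sb
        sum_s += sb.sum(axis=0)
    mean_r = sum_r / n
    mean_s = sum_s / n
    cov_rs = sum_rs / n - np.outer(mean_r, mean_s)
    var_r = sum_r2 / n - mean_r**2
    with np.errstate(invalid="ignore", divide="ignore"):
        fields = np.where(var_r[:, None] > 0, cov_rs / var_r[:, None], 0.0)
    return fields.reshape(-1, edge, edge)


def stc(model, unit, noise_images, layer: str = "z1", n_eig: int = 4,
        batch_size: int = 4096):
    """Spike-triggered covariance with mean and STA projected out.

    Eigen-decomposes the response-weighted stimulus covariance difference
    Delta-C = E[(r - rbar) s s^T] after removing the stimulus mean and the
    STA direction; leading eigenvectors span the unit's quadratic feature
    subspace.  Returns (eigenvalues, eigenvectors (D, n_eig), sta_field).
    """
    S = np.asarray(getattr(noise_images, "patches", noise_images),
                   dtype=np.float64)
    n, D = S.shape
    if n < 10 * D:
        warnings.warn(f"STC spectrum may be unstable: n={n} < 10 D={10 * D}")
    sta_field = sta(model, S, units=[unit], layer=layer,
                    batch_size=batch_size)[0].ravel()
    norm = np.linalg.norm(sta_field)
    u = sta_field / norm if norm > 0 else None
    if u is not None:
        # only project out a *significant* linear component: the STA of a
        # purely quadratic unit is noise biased toward the quadratic
        # subspace, and removing it would tilt the recovered eigenvectors.
        # Split-half check: STA direction from the first half, held-out
        # linear correlation on the second half
        half = n // 2
        u_half = sta(model, S[:half], units=[unit], layer=layer,
                     batch_size=batch_size)[0].ravel()
        nh = np.linalg.norm(u_half)
        if nh == 0:
            u = None
        else:
            r_test = np.concatenate([
                mean_path_responses(model, S[i:i + batch_size],
                                    layer=layer)[:, unit]
                for i in range(half, n, batch_size)])
            c = np.corrcoef(S[half:] @ (u_half / nh), r_test)[0, 1]
            if abs(c) < 3.0 / np.sqrt(n - half):
                u = None
    mean_s = S.mean(axis=0)
    C = np.zeros((D, D))
    sum_r = 0.0
    for start in range(0, n, batch_size):
        sb = S[start:start + batch_size] - mean_s
        if u is not None:
            sb = sb - np.outer(sb @ u, u)
        r = mean_path_responses(model, S[start:start + batch_size],
                                layer=layer)[:, unit]
        sum_r += r.sum()
        C += (sb * r[:, None]).T @ sb
    rbar = sum_r / n
    # subtract rbar * covariance of the projected stimuli
    Cs = np.zeros((D, D))
    for start in range(0, n, batch_size):
        sb = S[start:start + batch_size] - mean_s
        if u is not None:
            sb = sb - np.outer(sb @ u, u)
        Cs += sb.T @ sb
    dC = C / n - rbar * Cs / n
    evals, evecs = np.linalg.eigh(dC)
    order = np.argsort(np.abs(evals))[::-1][:n_eig]
    return evals[order], evecs[:, order], sta_field.reshape(
        int(np.sqrt(D)), int(np.sqrt(D)))


# ---------------------------------------------------------------------------
# projective fields and tuning


def projective_field(model, unit, layer: str = "z1", amplitude: float = 1.0,
                     n_decodes: int = 128, seed: int = 0) -> np.ndarray:
    """Latent-traversal field: mean decoded image difference at +/-amplitude.

    For Z1 units the decoder is linear, so the field equals
    2 * amplitude * (generative column of A) exactly.  For Z2 units the
    conditional p(Z1 | Z2) is sampled `n_decodes` times at each traversal
    point and the mean images are differenced.
    """
    edge = int(np.sqrt(model.n_features_in_))
    if layer == "z1":
        z = np.zeros((1, model.dim_z1))
        z[0, unit] = amplitude
        field = model.decode(z)[0] - model.decode(-z)[0]
        return field.reshape(edge, edge)
    rng = np.random.default_rng(seed)
    z2 = np.zeros((1, model.dim_z2))
    z2[0, unit] = amplitude
    means = []
    for sign in (1.0, -1.0):
        loc, sc = model.conditional_prior(sign * z2)
        from .dists import laplace_noise

        z1 = loc + sc * laplace_noise(rng, (n_decodes,) + loc.shape[-1:])
        means.append(model.decode(z1).mean(axis=0))
    return (means[0] - means[1]).reshape(edge, edge)


def orientation_tuning(model, unit, orientations=None, wavelength=None,
                       contrast: float = 1.0, n_phases: int = 16,
                       layer: str = "z1") -> TuningCurve:
    """Response amplitude (max - min over phase) at fixed wavelength/contrast."""
    from .stimuli import grating

    edge = int(np.sqrt(model.n_features_in_))
    if orientations is None:
        orientations = np.linspace(0, np.pi, 24, endpoint=False)
    if wavelength is None:
        wavelength = edge / 8.0
    phases = np.linspace(0, 2 * np.pi, n_phases, endpoint=False)
    amps = []
    for th in orientations:
        stims = np.stack([
            grating(th, ph, wavelength, contrast, edge).ravel()
            for ph in phases
        ])
        r = mean_path_responses(model, stims, layer=layer)[:, unit]
        amps.append(r.max() - r.min())
    return TuningCurve(np.asarray(orientations), np.asarray(amps))


# ---------------------------------------------------------------------------
# geometry


def rf_geometry(field: np.ndarray) -> ReceptiveFieldSummary:
    """Field geometry: squared-field center of mass, moment-matched
    envelope sigma, and the dominant Fourier component.

    The envelope sigma comes from matching the moment of inertia of the
    pointwise absolute field to that of a circular Gaussian profile
    (I = 2 sigma^2).  The dominant wave vector is the argmax of the FFT
    power over the non-DC half-plane, ties broken toward lower frequency.
    """
    field = np.asarray(field, dtype=np.float64)
    if np.all(field == 0):
        raise ValueError("zero field has no geometry")
    edge = field.shape[0]
    rows, cols = np.meshgrid(np.arange(edge), np.arange(edge), indexing="ij")
    w2 = field**2
    com_r = float(np.sum(rows * w2) / np.sum(w2))
    com_c = float(np.sum(cols * w2) / np.sum(w2))
    wabs = np.abs(field)
    r2 = (rows - com_r) ** 2 + (cols - com_c) ** 2
    inertia = float(np.sum(r2 * wabs) / np.sum(wabs))
    sigma = float(np.sqrt(inertia / 2.0))
    # dominant wave vector on the half-plane, DC excluded
    F = np.fft.fft2(field)
    P = np.abs(F) ** 2
    fr = np.fft.fftfreq(edge)
    KR, KC = np.meshgrid(fr, fr, indexing="ij")
    half = (KR > 0) | ((KR == 0) & (KC > 0))
    Pm = np.where(half, P, -np.inf)
    best = Pm.max()
    cand = np.argwhere(Pm >= best * (1 - 1e-12))
    mags = np.hypot(KR[cand[:, 0], cand[:, 1]], KC[cand[:, 0], cand[:, 1]])
    pick = cand[int(np.argmin(mags))]
    k = np.array([KR[pick[0], pick[1]], KC[pick[0], pick[1]]])
    kmag = float(np.hypot(*k))
    wavelength = float(1.0 / kmag) if kmag > 0 else np.inf
    # stripe orientation: perpendicular to the wave vector, in image (x, y)
    ori = float(np.mod(np.arctan2(k[0], k[1]) + np.pi / 2, np.pi))
    return ReceptiveFieldSummary(
        field=field,
        center_of_mass=(com_r, com_c),
        envelope_sigma=sigma,
        dominant_wave_vector=k,
        dominant_wavelength=wavelength,
        orientation=ori,
    )


# ---------------------------------------------------------------------------
# unit selection


def select_central_localized_medium(summaries, edge, center_frac: float = 0.4,
                                    sigma_range=(0.18, 0.33),
                                    wavelength_range=(0.17, 0.28)) -> np.ndarray:
    """Units with central, localized, medium-wavelength fields.

    Keeps units whose squared-field center of mass falls in the central
    (center_frac)^2 of the patch, whose envelope sigma is within
    `sigma_range` of the edge length, and whose dominant wavelength is
    within `wavelength_range` of the edge length.
    """
    lo = edge * (0.5 - center_frac / 2)
    hi = edge * (0.5 + center_frac / 2)
    keep = []
    for i, s in enumerate(summaries):
        r, c = s.center_of_mass
        central = lo <= r <= hi and lo <= c <= hi
        localized = sigma_range[0] * edge <= s.envelope_sigma <= sigma_range[1] * edge
        medium = (wavelength_range[0] * edge <= s.dominant_wavelength
                  <= wavelength_range[1] * edge)
        if central and localized and medium:
            keep.append(i)
    return np.asarray(keep, dtype=int)


def illusory_fit_criterion(sweep, edge, extension: float = 0.111) -> bool:
    """Aligned pac-man-center segment, extended both ways, fits the patch."""
    g = sweep.geometry
    e = g["edge_direction"]
    half = g["square_side"] / 2
    p0 = g["aligned_center"] - half * e
    p1 = g["aligned_center"] + half * e
    seg = p1 - p0
    q0 = p0 - extension * seg
    q1 = p1 + extension * seg
    return all(0 <= q[0] <= edge and 0 <= q[1] <= edge for q in (q0, q1))


def illusory_overlap_ratio(field, illusory_mask, line_mask) -> float:
    """Squared-field mass on the Illusory figure over mass on the Line figure."""
    f2 = np.asarray(field, dtype=np.float64) ** 2
    num = float(np.sum(f2 * illusory_mask))
    den = float(np.sum(f2 * line_mask))
    if den == 0:
        return np.inf
    return num / den


def peak_shift_spread(shifts, curves) -> float:
    """Largest pairwise distance between the argmax shifts of the curves."""
    peaks = [shifts[int(np.argmax(np.asarray(c)))] for c in curves]
    return float(max(peaks) - min(peaks))


def select_illusory_eligible(fields, sweeps, curve_sets, masks, edge,
                             overlap_threshold: float = 0.1,
                             extension: float = 0.111,
                             peak_tol: float = 0.25) -> np.ndarray:
    """Indices of units passing all three illusory-eligibility criteria.

    `masks[i]` supplies (illusory_mask, line_mask) final-resolution figure
    masks for unit i's aligned stimulus; `curve_sets[i]` is the list of
    response curves whose peak positions must agree to within `peak_tol`
    pixels.
    """
    keep = []
    for i, (field, sweep) in enumerate(zip(fields, sweeps)):
        if not sweep.eligible:
            continue
        if not illusory_fit_criterion(sweep, edge, extension):
            continue
        ill_mask, line_mask = masks[i]
        if illusory_overlap_ratio(field, ill_mask, line_mask) >= overlap_threshold:
            continue
        if peak_shift_spread(sweep.shifts, curve_sets[i]) > peak_tol:
            continue
        keep.append(i)
    return np.asarray(keep, dtype=int)
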
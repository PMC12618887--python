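"""Population-level statistics: comparison-dataset assembly, family
decoders, nested ANOVA, modulation indices, correlation analyses and
low-dimensional visualization prep.

The "comparison" dataset emulates a texture electrophysiology design: F
texture families x 15 samples x {intact, phase-scrambled} x 20
presentations, with a population of Z1 units and a population of Z2
pseudo-units (first components of random rotations of the active Z2
subspace, consistent with the rotation-invariant Z2 prior).  All units are
sampled with independent randomness so no cross-unit correlations are
induced by shared draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

from . import dists
from .inference import encode
from .stimuli import phase_scramble

__all__ = [
    "ComparisonDataset",
    "VariancePartition",
    "DecoderReport",
    "build_comparison_dataset",
    "logistic_family_decoder",
    "nested_anova",
    "gaussian_classification_decoder",
    "modulation_index",
    "noise_correlations",
    "signal_correlations",
    "correlation_dissimilarity",
    "tsne_prep",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class ComparisonDataset:
    """Responses to F x S x {intact, scrambled} x R texture presentations."""

    z1: np.ndarray          # (units, F, S, 2, R)
    z2: np.ndarray          # (pseudo-units, F, S, 2, R)
    z1_unit_ids: np.ndarray
    families: np.ndarray    # family id per F index
    seed: int = 0

    @property
    def n_families(self):
        return self.z1.shape[1]


@dataclass
class VariancePartition:
    across_families: np.ndarray   # percent, per unit
    across_samples: np.ndarray
    across_repetitions: np.ndarray
    f_family: np.ndarray
    f_sample: np.ndarray
    variance_ratio: np.ndarray    # across_families% / across_samples%
    capped: np.ndarray            # ratio overflow flags


@dataclass
class DecoderReport:
    accuracy_mean: float
    accuracy_sd: float
    n_seeds: int
    chance_level: float
    feature_source: str = ""


# ---------------------------------------------------------------------------
# comparison dataset


def _random_rotations(rng, dim, n):
    """Haar-distributed orthogonal matrices."""
    mats = []
    for _ in range(n):
        Q, R = np.linalg.qr(rng.standard_normal((dim, dim)))
        mats.append(Q * np.sign(np.diag(R)))
    return mats


def build_comparison_dataset(model, texture_patches, texture_labels,
                             active_z1, active_z2, n_z1_units: int = 100,
                             n_z2_units: int = 100, n_samples: int = 15,
                             n_reps: int = 20, seed: int = 0,
                             scramble_whitening=None) -> ComparisonDataset:
    """Assemble the texture comparison dataset from a trained model.

    Z1 responses mimic a 100 ms window: the mean of five conditional Z1
    draws under a single Z2 posterior draw.  Z2 pseudo-unit responses are
    first components of fresh orthogonal rotations of the active Z2
    subspace applied to one Z2 posterior draw.  Every unit gets
    independent randomness.  Phase-scrambled counterparts of each texture
    sample form the second stimulus condition; they are re-whitened with
    `scramble_whitening` when given.
    """
    rng = np.random.default_rng(seed)
    active_z1 = np.asarray(active_z1)
    active_z2 = np.asarray(active_z2)
    families = np.unique(texture_labels)
    F = len(families)
    edge = int(np.sqrt(texture_patches.shape[1]))
    if len(active_z1) >= n_z1_units:
        z1_ids = rng.choice(active_z1, size=n_z1_units, replace=False)
    else:
        warnings.warn("fewer active Z1 units than requested: sampling "
                      "with replacement")
        z1_ids = rng.choice(active_z1, size=n_z1_units, replace=True)
    dim_act2 = len(active_z2)
    rotations = _random_rotations(rng, dim_act2, n_z2_units)
    z1_resp = np.zeros((n_z1_units, F, n_samples, 2, n_reps))
    z2_resp = np.zeros((n_z2_units, F, n_samples, 2, n_reps))
    for fi, fam in enumerate(families):
        rows = np.flatnonzero(np.asarray(texture_labels) == fam)[:n_samples]
        for si, row in enumerate(rows):
            x = texture_patches[row]
            scr = phase_scramble(x.reshape(edge, edge),
                                 seed=int(rng.integers(2**31 - 1))).ravel()
            if scramble_whitening is not None:
                scr = scramble_whitening.transform(scr[None])[0]
            for ci, stim in enumerate((x, scr)):
                (mu2, s2), conditional = encode(stim, model)
                # Z1 units: per unit and repetition, one Z2 posterior draw
                # and the mean of five conditional Z1 draws under it
                m = n_z1_units * n_reps
                z2_draws = mu2 + s2 * rng.standard_normal((m, mu2.size))
                loc, sc = conditional(z2_draws)
                noise = dists.laplace_noise(rng, (5, m, loc.shape[1])).mean(axis=0)
                vals = loc + sc * noise
                cols = np.repeat(z1_ids, n_reps)
                z1_resp[:, fi, si, ci, :] = vals[np.arange(m), cols].reshape(
                    n_z1_units, n_reps)
                # Z2 pseudo-units: one independent posterior draw each, rotated
                z2_draw = mu2 + s2 * rng.standard_normal(
                    (n_z2_units * n_reps, mu2.size))
                act = z2_draw[:, active_z2].reshape(n_z2_units, n_reps, dim_act2)
                for u in range(n_z2_units):
                    z2_resp[u, fi, si, ci, :] = act[u] @ rotations[u][0]
    return ComparisonDataset(z1=z1_resp, z2=z2_resp, z1_unit_ids=z1_ids,
                             families=families, seed=seed)


# ---------------------------------------------------------------------------
# decoders


def logistic_family_decoder(features, labels, n_seeds: int = 5, C: float = 1.0,
                            test_size: float = 0.25, max_iter: int = 2000,
                            feature_source: str = "") -> DecoderReport:
    """Multinomial logistic regression family decoding accuracy.

    Reports mean and sd of held-out accuracy over `n_seeds` random
    initializations/splits; `C` is the inverse weight-decay strength.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    accs = []
    for s in range(n_seeds):
        Xtr, Xte, ytr, yte = train_test_split(
            features, labels, test_size=test_size, random_state=s,
            stratify=labels)
        clf = LogisticRegression(C=C, max_iter=max_iter, random_state=s)
        clf.fit(Xtr, ytr)
        accs.append(clf.score(Xte, yte))
    return DecoderReport(float(np.mean(accs)), float(np.std(accs)),
                         n_seeds, 1.0 / len(classes), feature_source)


def gaussian_classification_decoder(responses, task: str = "within_family_sample",
                                    population_sizes=(1, 3, 10, 30, 100),
                                    n_resamplings: int = 100, seed: int = 0,
                                    n_fit_reps: int = 4, n_fit_samples: int = 8,
                                    var_floor: float = 1e-6):
    """Gaussian maximum-likelihood decoding vs population size.

    `responses` is (units, F, S, R).  The sample task estimates per-sample
    response mean/variance from `n_fit_reps` random repetitions and
    classifies held-out repetitions among the S samples of the same family;
    the family task estimates family statistics from `n_fit_samples` random
    samples and classifies repetitions of held-out samples among families.
    Returns {population_size: mean accuracy}.
    """
    rng = np.random.default_rng(seed)
    R_ = np.asarray(responses, dtype=np.float64)
    U, F, S, R = R_.shape
    out = {}
    for pop in population_sizes:
        accs = []
        for _ in range(n_resamplings):
            units = rng.choice(U, size=min(pop, U), replace=False)
            rr = R_[units]
            if task == "within_family_sample":
                reps = rng.permutation(R)
                fit_r, test_r = reps[:n_fit_reps], reps[n_fit_reps:]
                mu = rr[:, :, :, fit_r].mean(axis=3)
                var = np.maximum(rr[:, :, :, fit_r].var(axis=3, ddof=1),
                                 var_floor)
                correct = total = 0
                for f in range(F):
                    x = rr[:, f, :, :][:, :, test_r]  # (units, S, ntest)
                    ll = -((x[:, None, :, :] - mu[:, f, :, None, None]) ** 2
                           / (2 * var[:, f, :, None, None])
                           + 0.5 * np.log(2 * np.pi * var[:, f, :, None, None]))
                    score = ll.sum(axis=0)  # (S_hyp, S_true, ntest)
                    pred = np.argmax(score, axis=0)
                    truth = np.arange(S)[:, None]
                    correct += np.sum(pred == truth)
                    total += pred.size
                accs.append(correct / total)
            elif task == "family":
                samp = rng.permutation(S)
                fit_s, test_s = samp[:n_fit_samples], samp[n_fit_samples:]
                pool = rr[:, :, fit_s, :].reshape(len(units), F, -1)
                mu = pool.mean(axis=2)
                var = np.maximum(pool.var(axis=2, ddof=1), var_floor)
                x = rr[:, :, test_s, :].reshape(len(units), F, -1)
                ll = -((x[:, None, :, :] - mu[:, :, None, None]) ** 2
                       / (2 * var[:, :, None, None])
                       + 0.5 * np.log(2 * np.pi * var[:, :, None, None]))
                score = ll.sum(axis=0)  # (F_hyp, F_true, n)
                pred = np.argmax(score, axis=0)
                truth = np.arange(F)[:, None]
                accs.append(np.mean(pred == truth))
            else:
                raise ValueError(f"unknown task {task!r}")
        out[pop] = float(np.mean(accs))
    return out


# ---------------------------------------------------------------------------
# nested ANOVA


def nested_anova(responses, ratio_cap: float = 1e6) -> VariancePartition:
    """Classical balanced two-level nested ANOVA per unit.

    `responses` is (units, F, S, R): samples nested in families,
    repetitions nested in samples.  Method-of-moments variance components
    are converted to percent shares; the variance ratio is
    across-family% / across-sample%, capped (and flagged) when the
    across-sample share vanishes.
    """
    X = np.asarray(responses, dtype=np.float64)
    if X.ndim != 4:
        raise ValueError("responses must be (units, families, samples, reps)")
    U, F, S, R = X.shape
    if F < 2 or S < 2 or R < 2:
        raise ValueError("need >= 2 levels at each nesting depth")
    grand = X.mean(axis=(1, 2, 3), keepdims=True)
    fam_mean = X.mean(axis=(2, 3), keepdims=True)
    samp_mean = X.mean(axis=3, keepdims=True)
    ss_fam = S * R * ((fam_mean - grand) ** 2).sum(axis=(1, 2, 3))
    ss_samp = R * ((samp_mean - fam_mean) ** 2).sum(axis=(1, 2, 3))
    ss_err = ((X - samp_mean) ** 2).sum(axis=(1, 2, 3))
    ms_fam = ss_fam / (F - 1)
    ms_samp = ss_samp / (F * (S - 1))
    ms_err = ss_err / (F * S * (R - 1))
    var_rep = ms_err
    var_samp = np.maximum((ms_samp - ms_err) / R, 0.0)
    var_fam = np.maximum((ms_fam - ms_samp) / (S * R), 0.0)
    total = var_rep + var_samp + var_fam
    total = np.where(total > 0, total, 1.0)
    p_fam = 100 * var_fam / total
    p_samp = 100 * var_samp / total
    p_rep = 100 * var_rep / total
    capped = p_samp <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(capped, ratio_cap, p_fam / np.where(capped, 1.0, p_samp))
        f_family = ms_fam / ms_samp
        f_sample = ms_samp / ms_err
    return VariancePartition(
        across_families=p_fam, across_samples=p_samp, across_repetitions=p_rep,
        f_family=f_family, f_sample=f_sample,
        variance_ratio=ratio, capped=capped)


def geometric_mean_ratio(partition: VariancePartition) -> float:
    """Population summary: geometric mean of per-unit variance ratios."""
    r = partition.variance_ratio
    r = r[np.isfinite(r) & (r > 0)]
    return float(np.exp(np.mean(np.log(r))))


# ---------------------------------------------------------------------------
# modulation index


def modulation_index(responses_intact, responses_scrambled):
    """Per-unit (a - b) / (a + b) contrast, averaged over families.

    Inputs are per-unit per-family mean response magnitudes (units, F).
    Families with a + b = 0 are excluded per unit with a warning; units
    with no valid family yield NaN.
    """
    a = np.asarray(responses_intact, dtype=np.float64)
    b = np.asarray(responses_scrambled, dtype=np.float64)
    s = a + b
    valid = s != 0
    if not np.all(valid):
        warnings.warn("undefined modulation indices (a + b = 0) excluded")
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.where(valid, (a - b) / np.where(valid, s, 1.0), np.nan)
    return np.nanmean(idx, axis=-1) if idx.ndim > 1 else idx


# ---------------------------------------------------------------------------
# correlations


def _pearson_matrix(X):
    """Rows = variables.  Zero-variance rows become NaN rows/cols."""
    X = np.asarray(X, dtype=np.float64)
    sd = X.std(axis=1)
    ok = sd > 0
    if not np.all(ok):
        warnings.warn("zero-variance units excluded from correlations")
    M = np.full((X.shape[0], X.shape[0]), np.nan)
    if ok.sum() >= 2:
        M_ok = np.corrcoef(X[ok])
        M[np.ix_(ok, ok)] = M_ok
    M[np.diag_indices_from(M)] = 1.0
    return M


def noise_correlations(response_matrix) -> np.ndarray:
    """Pearson correlations across trials of one stimulus (units x units)."""
    values = np.asarray(getattr(response_matrix, "values", response_matrix))
    if values.ndim != 2:
        raise ValueError("expected a units x trials matrix for one stimulus")
    if values.shape[1] < 2:
        raise ValueError("need >= 2 trials")
    return _pearson_matrix(values)


def signal_correlations(mean_responses) -> np.ndarray:
    """Pearson correlations across samples of trial-averaged responses."""
    values = np.asarray(mean_responses, dtype=np.float64)
    if values.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    return _pearson_matrix(values)


def correlation_dissimilarity(M1, M2) -> float:
    """Mean absolute difference over the off-diagonal upper triangle."""
    M1, M2 = np.asarray(M1), np.asarray(M2)
    if M1.shape != M2.shape:
        raise ValueError("matrices differ in shape")
    iu = np.triu_indices(M1.shape[0], k=1)
    a, b = M1[iu], M2[iu]
    ok = np.isfinite(a) & np.isfinite(b)
    if not np.any(ok):
        raise ValueError("no valid entries to compare")
    return float(np.mean(np.abs(a[ok] - b[ok])))


# ---------------------------------------------------------------------------
# visualization prep


def tsne_prep(mean_responses):
    """Z-score each unit across stimuli; constant units are dropped.

    `mean_responses` is (stimuli, units); the normalized matrix is ready
    for a t-SNE embedding (perplexity 30 in the standard configuration).
    """
    X = np.asarray(mean_responses, dtype=np.float64)
    sd = X.std(axis=0)
    keep = sd > 0
    if not np.all(keep):
        warnings.warn(f"dropping {np.sum(~keep)} constant units")
    X = X[:, keep]
    return (X - X.mean(axis=0)) / X.std(axis=0)
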
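"""Top-down experiments: illusory-contour sweeps, pre/early/late time
courses, contour completion, and severed-feedback texture decoding.

A single mechanism — stimulus-specific information reaching Z1 through the
top-down pathway — underlies all four observables probed here.  Severing
the feedback (zeroing the Z2 -> L_z map) removes illusory boosting, the
early/late difference, above-floor family decodability of Z1, and the
off-diagonal Z1 covariance induced by Z2 variability.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .inference import WindowScheme, marginal_z1_mean, sample_responses
from .population import DecoderReport, logistic_family_decoder

__all__ = [
    "IllusoryResult",
    "TIMECOURSE_CONDITIONS",
    "sever_feedback",
    "linear_response",
    "run_illusory_experiment",
    "run_timecourse",
    "run_contour_experiment",
    "severed_feedback_decoding",
]

# pre-stimulus, early (stimulus at Z1, prior at Z2), late (full inference)
TIMECOURSE_CONDITIONS = {"pre": "prior_both", "early": "prior_z2",
                         "late": "intact"}


@dataclass
class IllusoryResult:
    shifts: np.ndarray
    curves: dict            # type -> mean curve over trials
    sems: dict              # type -> sem curve
    linear_curves: dict     # type -> scaled linear curve
    line_peak_shift: float
    line_peak_index: int
    ratio_illusory: float   # Illusory / Line at the Line peak
    ratio_rotated: float
    boosting: float         # mean(model - linear) at Illusory, Line peak
    boosting_t: float
    boosting_p: float       # one-sided (boosting > 0)
    condition: str = "intact"
    unit: int | None = None


def sever_feedback(model):
    """Copy of a hierarchical model with the top-down pathway zeroed."""
    cut = copy.deepcopy(model)
    if getattr(cut, "z1_td_", None) is not None:
        for W, b in cut.z1_td_.layers:
            W.data[:] = 0.0
            b.data[:] = 0.0
    return cut


def linear_response(unit_filter, stimuli, scaling: float = 1.0) -> np.ndarray:
    """Inner product of the unit's filter with each stimulus, times `scaling`."""
    f = np.asarray(unit_filter, dtype=np.float64).ravel()
    S = np.asarray(stimuli, dtype=np.float64).reshape(len(stimuli), -1)
    return scaling * (S @ f)


def _response_curves(model, stims, scheme, n_trials, condition, seed, unit):
    X = stims.reshape(len(stims), -1)
    rm = sample_responses(X, model, scheme=scheme, n_trials=n_trials,
                          condition=condition, seed=seed, units=[unit])
    vals = rm.values[0]  # (trials, shifts)
    return vals, vals.mean(axis=0), vals.std(axis=0, ddof=1) / np.sqrt(n_trials)


def run_illusory_experiment(model, unit, sweep, unit_filter,
                            n_trials: int = 500,
                            scheme: WindowScheme = WindowScheme(1, 3),
                            condition: str = "intact",
                            seed: int = 0) -> IllusoryResult:
    """Windowed responses over a Kanizsa sweep with linear-response control.

    The linear curve is the filter inner product, scaled with one factor
    chosen so the Line linear-curve peak equals the Line model-curve peak.
    The boosting score is the mean over trials of (model - linear) for the
    Illusory stimulus at the Line-curve peak shift, with a one-sided
    one-sample t-test against zero.
    """
    curves, sems, trials = {}, {}, {}
    for i, t in enumerate(("Line", "Illusory", "Rotated")):
        vals, mean, sem = _response_curves(model, sweep.stimuli[t], scheme,
                                           n_trials, condition, seed + i, unit)
        trials[t], curves[t], sems[t] = vals, mean, sem
    raw_linear = {t: linear_response(unit_filter, sweep.stimuli[t])
                  for t in curves}
    line_peak_idx = int(np.argmax(curves["Line"]))
    line_peak = curves["Line"][line_peak_idx]
    lin_peak = raw_linear["Line"].max()
    if lin_peak == 0:
        raise ValueError("zero Line linear peak: cannot scale linear response")
    factor = line_peak / lin_peak
    linear_curves = {t: factor * raw_linear[t] for t in raw_linear}
    diffs = trials["Illusory"][:, line_peak_idx] \
        - linear_curves["Illusory"][line_peak_idx]
    tstat, p_two = sps.ttest_1samp(diffs, 0.0)
    p_one = p_two / 2 if tstat > 0 else 1 - p_two / 2
    line_val = curves["Line"][line_peak_idx]
    return IllusoryResult(
        shifts=sweep.shifts,
        curves=curves, sems=sems, linear_curves=linear_curves,
        line_peak_shift=float(sweep.shifts[line_peak_idx]),
        line_peak_index=line_peak_idx,
        ratio_illusory=float(curves["Illusory"][line_peak_idx] / line_val),
        ratio_rotated=float(curves["Rotated"][line_peak_idx] / line_val),
        boosting=float(np.mean(diffs)),
        boosting_t=float(tstat), boosting_p=float(p_one),
        condition=condition, unit=unit,
    )


def run_timecourse(model, unit, sweep, unit_filter, n_trials: int = 500,
                   scheme: WindowScheme = WindowScheme(1, 3), seed: int = 0):
    """Illusory analysis under pre/early/late feedback conditions.

    All conditions share the same stimuli and unit; only the Z2 source
    changes (prior for both layers, prior for Z2 only, or full inference).
    Returns {label: IllusoryResult}.
    """
    return {
        label: run_illusory_experiment(
            model, unit, sweep, unit_filter, n_trials=n_trials, scheme=scheme,
            condition=cond, seed=seed)
        for label, cond in TIMECOURSE_CONDITIONS.items()
    }


def run_contour_experiment(model, unit, random_set, parallel_set, unit_filter,
                           n_trials: int = 30,
                           scheme: WindowScheme = WindowScheme(1, 3),
                           condition: str = "intact", seed: int = 0,
                           denom_floor: float = 1e-9):
    """Per-unit contour-completion effect score.

    For paired stimulus draws i: (trial-averaged three-parallel response /
    trial-averaged random response) - (three-parallel linear / random
    linear), averaged over draws; draws with near-zero denominators are
    excluded and counted.  Returns (effect, n_excluded, per-draw effects).
    """
    rnd = random_set.stimuli.reshape(len(random_set.stimuli), -1)
    par = parallel_set.stimuli.reshape(len(parallel_set.stimuli), -1)
    n = min(len(rnd), len(par))
    r_rnd = sample_responses(rnd[:n], model, scheme=scheme, n_trials=n_trials,
                             condition=condition, seed=seed,
                             units=[unit]).values[0].mean(axis=0)
    r_par = sample_responses(par[:n], model, scheme=scheme, n_trials=n_trials,
                             condition=condition, seed=seed + 1,
                             units=[unit]).values[0].mean(axis=0)
    l_rnd = linear_response(unit_filter, rnd[:n])
    l_par = linear_response(unit_filter, par[:n])
    ok = (np.abs(r_rnd) > denom_floor) & (np.abs(l_rnd) > denom_floor)
    effects = r_par[ok] / r_rnd[ok] - l_par[ok] / l_rnd[ok]
    return float(np.mean(effects)), int(np.sum(~ok)), effects


def severed_feedback_decoding(model, texture_patches, texture_labels,
                              active_z1=None, n_seeds: int = 5,
                              n_mc: int = 10, seed: int = 0):
    """Family decoding from Z1 marginal means: intact vs prior-Z2 feedback.

    Features are marginal Z1 posterior means computed with the Z2 source
    either the posterior (intact) or the prior (severed stimulus-specific
    feedback).  Returns (intact report, severed report, one-sided paired
    t-test p for intact > severed).
    """
    X = np.asarray(texture_patches, dtype=np.float64)
    feats = {}
    for label, condition in (("intact", "intact"), ("severed", "prior_z2")):
        rows = []
        for x in X:
            mean, _ = marginal_z1_mean(x, model, n_mc=n_mc, seed=seed,
                                       condition=condition, units=active_z1)
            rows.append(mean)
        feats[label] = np.asarray(rows)
    rep_intact = _per_seed_decoder(feats["intact"], texture_labels, n_seeds,
                                   "z1_means_intact")
    rep_severed = _per_seed_decoder(feats["severed"], texture_labels, n_seeds,
                                    "z1_means_prior_z2")
    a = np.asarray(rep_intact.pop("accs"))
    b = np.asarray(rep_severed.pop("accs"))
    tstat, p_two = sps.ttest_rel(a, b)
    p_one = p_two / 2 if tstat > 0 else 1 - p_two / 2
    return (DecoderReport(**rep_intact), DecoderReport(**rep_severed),
            float(p_one))


def _per_seed_decoder(features, labels, n_seeds, tag):
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split

    accs = []
    for s in range(n_seeds):
        Xtr, Xte, ytr, yte = train_test_split(
            features, labels, test_size=0.25, random_state=s, stratify=labels)
        clf = LogisticRegression(max_iter=2000, random_state=s).fit(Xtr, ytr)
        accs.append(clf.score(Xte, yte))
    return {"accuracy_mean": float(np.mean(accs)),
            "accuracy_sd": float(np.std(accs)), "n_seeds": n_seeds,
            "chance_level": 1.0 / len(np.unique(labels)),
            "feature_source": tag, "accs": accs}
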
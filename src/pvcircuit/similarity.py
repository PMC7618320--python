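"""Pairwise functional-similarity metrics between cells.

All cosine metrics operate on dF/F tensors or trial-average responses over
the same stimulus ensemble; correlations are Pearson coefficients of the
same quantities after mean subtraction.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "total_similarity",
    "response_similarity",
    "signal_similarity_time_avg",
    "total_correlation",
    "signal_correlation",
    "feature_deltas",
    "delta_ori",
    "marginal_tuning_correlations",
    "exclude_close_pairs",
]


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return np.nan
    return float(np.dot(u, v) / (nu * nv))


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    if np.std(u) == 0 or np.std(v) == 0:
        return np.nan
    return float(np.corrcoef(u, v)[0, 1])


def total_similarity(f: np.ndarray, f2: np.ndarray) -> float:
    """Per-segment cosine of single-trial dF/F traces, averaged over segments.

    ``f``, ``f2`` are (n_stim, n_rep, n_frames) tensors; segment j compares
    the flattened single-trial traces of repetition j.  Zero-norm segments
    are skipped (logged).
    """
    f = np.asarray(f, float)
    f2 = np.asarray(f2, float)
    if f.shape != f2.shape:
        raise ValueError("tensor shapes differ")
    vals = []
    for j in range(f.shape[1]):
        c = _cosine(f[:, j, :].ravel(), f2[:, j, :].ravel())
        if np.isnan(c):
            logger.warning("zero-norm segment %d skipped in total_similarity", j)
            continue
        vals.append(c)
    return float(np.mean(vals)) if vals else np.nan


def response_similarity(r: np.ndarray, r2: np.ndarray) -> float:
    """Cosine similarity of trial-average responses r(i, t)."""
    r = np.asarray(r, float)
    r2 = np.asarray(r2, float)
    if r.shape != r2.shape:
        raise ValueError("response shapes differ")
    return _cosine(r.ravel(), r2.ravel())


def signal_similarity_time_avg(rbar: np.ndarray, rbar2: np.ndarray) -> float:
    """Cosine similarity of time-averaged per-stimulus responses rbar(i)."""
    return _cosine(np.asarray(rbar, float).ravel(), np.asarray(rbar2, float).ravel())


def total_correlation(f: np.ndarray, f2: np.ndarray) -> float:
    """Per-segment Pearson correlation of single-trial traces, averaged."""
    f = np.asarray(f, float)
    f2 = np.asarray(f2, float)
    if f.shape != f2.shape:
        raise ValueError("tensor shapes differ")
    vals = []
    for j in range(f.shape[1]):
        c = _pearson(f[:, j, :].ravel(), f2[:, j, :].ravel())
        if np.isnan(c):
            logger.warning("zero-variance segment %d skipped in total_correlation", j)
            continue
        vals.append(c)
    return float(np.mean(vals)) if vals else np.nan


def signal_correlation(r: np.ndarray, r2: np.ndarray) -> float:
    """Pearson correlation of trial-average responses r(i, t)."""
    return _pearson(np.asarray(r, float).ravel(), np.asarray(r2, float).ravel())


def delta_ori(theta_pref_a: float, theta_pref_b: float) -> float:
    """Orientation difference in degrees, wrapped onto [0, 90].

    Preferred orientations are the preferred directions mod 180; the
    difference is 90 - ||phi - phi'| - 90|.
    """
    phi_a = theta_pref_a % 180.0
    phi_b = theta_pref_b % 180.0
    return float(90.0 - abs(abs(phi_a - phi_b) - 90.0))


def feature_deltas(params_a, params_b) -> dict[str, float]:
    """Per-feature preference differences of two tuning fits.

    Returns delta_sf, delta_tf, delta_speed (octaves) and delta_ori (deg).
    Speed preference is TF_pref - SF_pref in octave coordinates.
    """
    dsf = abs(params_a.sf_pref - params_b.sf_pref)
    dtf = abs(params_a.tf_pref - params_b.tf_pref)
    dspeed = abs((params_a.tf_pref - params_a.sf_pref)
                 - (params_b.tf_pref - params_b.sf_pref))
    return {
        "delta_sf": float(dsf),
        "delta_tf": float(dtf),
        "delta_speed": float(dspeed),
        "delta_ori": delta_ori(params_a.theta_pref, params_b.theta_pref),
    }


def marginal_tuning_correlations(
    rbar_a: np.ndarray,
    rbar_b: np.ndarray,
    shape: tuple[int, int, int] = (8, 6, 6),
) -> dict[str, float]:
    """Pearson correlation of single-feature tuning curves.

    ``rbar_*`` are per-stimulus mean responses, flattenable to the
    (direction, SF, TF) grid ``shape``; each marginal averages over the
    other two stimulus dimensions.  Zero-variance marginals give NaN.
    """
    a = np.asarray(rbar_a, float).reshape(shape)
    b = np.asarray(rbar_b, float).reshape(shape)
    return {
        "dir_corr": _pearson(a.mean(axis=(1, 2)), b.mean(axis=(1, 2))),
        "sf_corr": _pearson(a.mean(axis=(0, 2)), b.mean(axis=(0, 2))),
        "tf_corr": _pearson(a.mean(axis=(0, 1)), b.mean(axis=(0, 1))),
    }


def exclude_close_pairs(
    pos_a: np.ndarray,
    pos_b: np.ndarray,
    plane_a: np.ndarray,
    plane_b: np.ndarray,
    min_dist_um: float = 10.0,
) -> np.ndarray:
    """Mask of pairs to KEEP under the overlapping-ROI exclusion rule.

    A pair is dropped when the cells' lateral separation is below
    ``min_dist_um`` and they sit in the same or adjacent imaging planes
    (cross-talk between overlapping ROIs would inflate similarity).
    """
    pos_a = np.atleast_2d(np.asarray(pos_a, float))
    pos_b = np.atleast_2d(np.asarray(pos_b, float))
    lateral = np.linalg.norm(pos_a[:, :2] - pos_b[:, :2], axis=1)
    adjacent = np.abs(np.asarray(plane_a) - np.asarray(plane_b)) <= 1
    return ~((lateral < min_dist_um) & adjacent)
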
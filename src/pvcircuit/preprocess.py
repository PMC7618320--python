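"""Fluorescence trace conditioning and in vivo / in vitro coordinate registration."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

__all__ = [
    "detrend",
    "estimate_f0",
    "dff",
    "neuropil_correct",
    "AffineTransform",
    "fit_affine",
]


def detrend(values: np.ndarray, window: int = 500, percentile: float = 40.0) -> np.ndarray:
    """Remove slow drift: subtract the running percentile less its median.

    The running percentile is computed in a centered window, truncated at the
    trace boundaries (no padding).  A window longer than the trace falls back
    to the global percentile (logged); the output then equals the input.
    """
    x = np.asarray(values, float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite values")
    if window > x.size:
        logger.warning("detrend window %d exceeds trace length %d; "
                       "using global percentile", window, x.size)
        rp = np.full_like(x, np.percentile(x, percentile))
    else:
        rp = (pd.Series(x)
              .rolling(window, center=True, min_periods=1)
              .quantile(percentile / 100.0)
              .to_numpy())
    return x - (rp - np.median(rp))


def estimate_f0(
    values: np.ndarray,
    component: str = "smaller_mean",
    n_init: int = 10,
    seed: int = 0,
) -> float:
    """Baseline fluorescence from a two-Gaussian mixture of trace values.

    Fits by EM (k-means initialized, ``n_init`` restarts, best likelihood
    kept) and returns the mean of the component selected by ``component``:
    ``'smaller_mean'`` (default, the baseline component) or
    ``'smaller_weight'``.
    """
    x = np.asarray(values, float)
    if x.size < 100:
        raise ValueError("need at least 100 samples to estimate F0")
    if np.std(x) == 0:
        return float(x[0])
    gm = GaussianMixture(n_components=2, n_init=n_init,
                         init_params="kmeans", random_state=seed)
    gm.fit(x.reshape(-1, 1))
    means = gm.means_.ravel()
    if component == "smaller_mean":
        idx = int(np.argmin(means))
    elif component == "smaller_weight":
        idx = int(np.argmin(gm.weights_))
    else:
        raise ValueError(f"unknown component rule {component!r}")
    return float(means[idx])


def dff(values: np.ndarray, f0: float) -> np.ndarray:
    """dF/F: (F - F0) / F0 elementwise."""
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    return (np.asarray(values, float) - f0) / f0


def neuropil_correct(roi: np.ndarray, surround: np.ndarray, coeff: float = 0.7) -> np.ndarray:
    """Scalar-subtraction neuropil surrogate: roi - coeff * surround.

    Placeholder for a full neuropil model; accepts pre-corrected traces when
    ``coeff`` is 0.
    """
    return np.asarray(roi, float) - coeff * np.asarray(surround, float)


@dataclass
class AffineTransform:
    """3-D affine map x -> A x + b with residual diagnostics."""

    matrix: np.ndarray   # (3, 3)
    offset: np.ndarray   # (3,)
    rms: float = 0.0
    forward: bool = True

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, float))
        return pts @ self.matrix.T + self.offset

    def invert(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.offset, self.rms, not self.forward)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self after other: x -> self(other(x))."""
        return AffineTransform(self.matrix @ other.matrix,
                               self.matrix @ other.offset + self.offset,
                               max(self.rms, other.rms), self.forward)


def fit_affine(src_points: np.ndarray, dst_points: np.ndarray) -> AffineTransform:
    """Least-squares affine from >= 4 non-coplanar control-point pairs.

    Minimizes sum ||A src + b - dst||^2; the residual RMS is stored on the
    returned transform.
    """
    src = np.atleast_2d(np.asarray(src_points, float))
    dst = np.atleast_2d(np.asarray(dst_points, float))
    if src.shape != dst.shape or src.shape[1] != 3:
        raise ValueError("control points must be matching (n, 3) arrays")
    if src.shape[0] < 4:
        raise ValueError(f"need at least 4 control points, got {src.shape[0]}")
    centered = src - src.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("control points are coplanar; affine is underdetermined")
    design = np.hstack([src, np.ones((src.shape[0], 1))])
    sol, *_ = np.linalg.lstsq(design, dst, rcond=None)
    matrix = sol[:3].T
    offset = sol[3]
    resid = design @ sol - dst
    rms = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))
    return AffineTransform(matrix, offset, rms)
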
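"""Responsiveness, selectivity, and the constrained direction x SF/TF tuning model.

The tuning surface is the product of a double Gaussian in direction space
(peaked at the preferred direction, with a relative null-direction response
``q``) and a 2-D Gaussian over spatial/temporal frequency in octave
coordinates, rotated by an angle ``alpha``, plus an additive offset ``b``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import least_squares

from .ensemble import StimulusEnsemble

__all__ = [
    "TuningParams",
    "TuningBounds",
    "TuningFit",
    "predict_response",
    "variance_explained",
    "classify_responsive",
    "stimulus_means",
    "trial_moving_means",
    "selectivity_skewness",
    "fit_tuning",
    "fwhm_features",
    "RESPONSIVE_THRESHOLD",
]

#: Fraction of stimulus-explained variance above which a cell is "responsive".
RESPONSIVE_THRESHOLD = 0.15

#: Direction FWHM conversion factor, 2*sqrt(2*ln 2) rounded as conventionally used.
FWHM_FACTOR = 2.355

#: SF/TF ranges (physical units) over which FWHM curves are evaluated.
FWHM_SF_RANGE_CPD = (0.0025, 2.56)
FWHM_TF_RANGE_HZ = (0.125, 16.0)


@dataclass
class TuningParams:
    """The 9 parameters of the direction x SF/TF response model.

    Frequencies are in octaves relative to the lowest probed value; angles
    in degrees.
    """

    b: float = 0.0          # response offset
    r_max: float = 1.0      # response at preferred direction/SF/TF
    sf_pref: float = 2.0    # octaves
    tf_pref: float = 2.0    # octaves
    alpha: float = 0.0      # SF/TF Gaussian orientation, deg in [0, 90]
    sigma_x: float = 1.0    # octaves in [0.25, 4]
    sigma_y: float = 1.0    # octaves in [0.25, 4]
    sigma_dir: float = 30.0  # deg in [0, 180]
    q: float = 0.0          # null-direction ratio in [0, 1]
    theta_pref: float = 0.0  # deg in [0, 360)

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.b, self.r_max, self.sf_pref, self.tf_pref, self.alpha,
             self.sigma_x, self.sigma_y, self.sigma_dir, self.q, self.theta_pref]
        )

    @classmethod
    def from_array(cls, x: np.ndarray) -> "TuningParams":
        return cls(*(float(v) for v in x))

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class TuningBounds:
    """Box constraints of the fit (the parameter table of the model).

    ``r_max`` is bounded above by ``2 * max(r_ij)`` of the data being fit;
    SF/TF preferences must lie within one octave of the probed range.
    """

    ensemble: StimulusEnsemble
    r_max_cap: float

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        sf_oct = self.ensemble.sf_octaves
        tf_oct = self.ensemble.tf_octaves
        lo = np.array([-np.inf, 1e-9, sf_oct.min() - 1, tf_oct.min() - 1,
                       0.0, 0.25, 0.25, 1e-6, 0.0, 0.0])
        hi = np.array([np.inf, self.r_max_cap, sf_oct.max() + 1, tf_oct.max() + 1,
                       90.0, 4.0, 4.0, 180.0, 1.0, 360.0])
        if np.any(lo > hi):
            raise ValueError("invalid tuning bounds: lower bound exceeds upper")
        return lo, hi


def _wrapped_sq(delta_rad: np.ndarray) -> np.ndarray:
    """h(theta): squared angular difference wrapped onto [0, pi].

    The input is first reduced mod 2*pi so the wrap is exact for any angle
    (the q term offsets differences by pi, which can push them past 2*pi).
    """
    d = np.mod(np.abs(delta_rad), 2 * np.pi)
    return np.minimum(d, 2 * np.pi - d) ** 2


def _direction_factor(theta_deg, theta_pref_deg, sigma_dir_deg, q):
    # Exponent convention: exp(-h(dtheta) / (2 sigma^2)), sigma in radians.
    # Kept in one place because the rendering of the factor 2 is a modelling
    # choice; changing it here changes every consumer consistently.
    dt = np.deg2rad(np.asarray(theta_deg, float) - theta_pref_deg)
    s2 = max(np.deg2rad(sigma_dir_deg), 1e-12) ** 2
    return (np.exp(-_wrapped_sq(dt) / (2 * s2))
            + q * np.exp(-_wrapped_sq(dt + np.pi) / (2 * s2)))


def predict_response(params: TuningParams, theta_deg, sf_oct, tf_oct) -> np.ndarray:
    """Predicted mean moving-phase response for stimuli (direction, SF, TF).

    Inputs broadcast; frequencies are octave coordinates on the same scale
    as ``params.sf_pref`` / ``params.tf_pref``.
    """
    a = np.deg2rad(params.alpha)
    dsf = np.asarray(sf_oct, float) - params.sf_pref
    dtf = np.asarray(tf_oct, float) - params.tf_pref
    x = np.cos(a) * dsf + np.sin(a) * dtf
    y = -np.sin(a) * dsf + np.cos(a) * dtf
    gauss = np.exp(-(x ** 2 / (2 * params.sigma_x ** 2)
                     + y ** 2 / (2 * params.sigma_y ** 2)))
    dirfac = _direction_factor(theta_deg, params.theta_pref, params.sigma_dir, params.q)
    return params.r_max * dirfac * gauss + params.b


def variance_explained(f: np.ndarray) -> float:
    """Fraction of dF/F variance explained by the visual stimulus.

    ``f`` has shape (n_stim, n_rep, n_frames).  R^2 = 1 - Var(f - fbar)/Var(f)
    with fbar the trial average and variances taken over every sample.
    """
    f = np.asarray(f, float)
    if f.ndim != 3 or f.shape[1] < 2:
        raise ValueError("need a (n_stim, n_rep>=2, n_frames) tensor")
    total = np.var(f)
    if total == 0:
        warnings.warn("zero total variance; responsiveness undefined")
        return -np.inf
    fbar = f.mean(axis=1, keepdims=True)
    return 1.0 - np.var(f - fbar) / total


def classify_responsive(f: np.ndarray, threshold: float = RESPONSIVE_THRESHOLD) -> bool:
    r2 = variance_explained(f)
    return bool(r2 > threshold)


def stimulus_means(f: np.ndarray, moving_window: tuple[int, int]):
    """Trial-average response r(i, t) and moving-phase mean rbar(i).

    ``moving_window`` = (a, b), 0-based inclusive frame indices.
    """
    f = np.asarray(f, float)
    r_it = f.mean(axis=1)
    a, b = moving_window
    rbar = r_it[:, a:b + 1].mean(axis=1)
    return r_it, rbar


def trial_moving_means(f: np.ndarray, moving_window: tuple[int, int]) -> np.ndarray:
    """Single-trial moving-phase means r(i, j)."""
    a, b = moving_window
    return np.asarray(f, float)[:, :, a:b + 1].mean(axis=2)


def selectivity_skewness(rbar: np.ndarray) -> float:
    """Selectivity as the skewness of per-stimulus mean responses.

    Population moments (1/N) are used: m3 / m2^(3/2).
    """
    rbar = np.asarray(rbar, float)
    if rbar.size < 3:
        raise ValueError("need at least 3 stimulus types")
    d = rbar - rbar.mean()
    m2 = np.mean(d ** 2)
    if m2 == 0:
        raise ValueError("zero variance of stimulus means; skewness undefined")
    return float(np.mean(d ** 3) / m2 ** 1.5)


@dataclass
class TuningFit:
    params: TuningParams
    sse: float
    converged: bool = True
    fwhm_dir: float = np.nan
    fwhm_sf: float = np.nan
    fwhm_tf: float = np.nan
    tuned_dir: bool = False
    tuned_sf: bool = False
    tuned_tf: bool = False
    fwhm_clipped: bool = False
    n_restarts: int = 0


def _residuals(x, theta, sf, tf, r):
    return predict_response(TuningParams.from_array(x), theta, sf, tf) - r


def fit_tuning(
    f: np.ndarray,
    ensemble: StimulusEnsemble,
    n_restarts: int = 50,
    seed: int | np.random.Generator = 0,
    with_fwhm: bool = True,
) -> TuningFit:
    """Bound-constrained least-squares fit of the tuning model.

    Fits the single-trial moving-phase means r(i, j) of a (n_stim, n_rep,
    n_frames) tensor by multi-start trust-region-reflective least squares;
    the best SSE over restarts is kept.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    r_ij = trial_moving_means(f, ensemble.moving_window)
    theta, sf, tf = ensemble.grid()
    n_rep = r_ij.shape[1]
    theta_r = np.repeat(theta, n_rep)
    sf_r = np.repeat(sf, n_rep)
    tf_r = np.repeat(tf, n_rep)
    r_flat = r_ij.ravel()

    r_cap = 2.0 * max(r_ij.max(), 1e-6)
    lo, hi = TuningBounds(ensemble, r_cap).arrays()
    b_lo, b_hi = r_flat.min() - 1.0, r_flat.max() + 1.0
    lo[0], hi[0] = b_lo, b_hi

    best = None
    n_ok = 0
    for _ in range(n_restarts):
        x0 = np.empty(10)
        x0[0] = rng.uniform(r_flat.min(), r_flat.max() + 1e-9)
        x0[1] = rng.uniform(0.05 * r_cap, r_cap)
        x0[2:] = rng.uniform(lo[2:], hi[2:])
        try:
            res = least_squares(
                _residuals, x0, bounds=(lo, hi),
                args=(theta_r, sf_r, tf_r, r_flat), method="trf",
                xtol=1e-10, ftol=1e-10,
            )
        except Exception:
            continue
        if not res.success:
            continue
        n_ok += 1
        sse = float(2 * res.cost)
        if best is None or sse < best[0]:
            best = (sse, res.x)

    if best is None:
        return TuningFit(TuningParams(), np.inf, converged=False, n_restarts=n_restarts)
    fit = TuningFit(TuningParams.from_array(best[1]), best[0],
                    converged=True, n_restarts=n_ok)
    if with_fwhm:
        fwhm_features(fit, ensemble)
    return fit


def _curve_fwhm(grid: np.ndarray, curve: np.ndarray, b: float) -> tuple[float, bool]:
    """Width of the region around the peak above half max (measured above b).

    Returns (width, clipped): ``clipped`` is True when the curve never falls
    to the half level inside the grid on one or both sides, in which case the
    crossing is clamped to the range edge.
    """
    k = int(np.argmax(curve))
    peak = curve[k]
    if peak <= b:
        return grid[-1] - grid[0], True
    half = b + (peak - b) / 2.0
    clipped = False
    # walk left
    i = k
    while i > 0 and curve[i - 1] >= half:
        i -= 1
    if i == 0:
        left, clipped = grid[0], True
    else:
        t = (half - curve[i - 1]) / (curve[i] - curve[i - 1])
        left = grid[i - 1] + t * (grid[i] - grid[i - 1])
    # walk right
    j = k
    n = len(curve)
    while j < n - 1 and curve[j + 1] >= half:
        j += 1
    if j == n - 1:
        right, clipped = grid[-1], True
    else:
        t = (half - curve[j + 1]) / (curve[j] - curve[j + 1])
        right = grid[j + 1] - t * (grid[j + 1] - grid[j])
    return float(right - left), clipped


def fwhm_features(
    fit: TuningFit,
    ensemble: StimulusEnsemble,
    grid_step_oct: float = 0.05,
) -> TuningFit:
    """Full-width-at-half-maximum features and tuned/untuned flags (in place).

    Direction FWHM is 2.355 * sigma_dir.  SF and TF FWHMs come from the
    half-maximum crossings (measured above the offset ``b``) of the predicted
    curve on a dense log2 grid over the standard evaluation ranges, holding
    the other features at their preferred values.  Cells with direction FWHM
    > 180 deg or frequency FWHM > 6 octaves are flagged untuned.
    """
    p = fit.params
    fit.fwhm_dir = FWHM_FACTOR * p.sigma_dir
    fit.tuned_dir = fit.fwhm_dir <= 180.0

    sf0 = ensemble.spatial_freqs[0]
    tf0 = ensemble.temporal_freqs[0]
    sf_lo, sf_hi = (np.log2(v / sf0) for v in FWHM_SF_RANGE_CPD)
    tf_lo, tf_hi = (np.log2(v / tf0) for v in FWHM_TF_RANGE_HZ)

    clipped = False
    sf_grid = np.arange(sf_lo, sf_hi + grid_step_oct / 2, grid_step_oct)
    curve = predict_response(p, p.theta_pref, sf_grid, p.tf_pref)
    fit.fwhm_sf, c = _curve_fwhm(sf_grid, curve, p.b)
    clipped |= c
    tf_grid = np.arange(tf_lo, tf_hi + grid_step_oct / 2, grid_step_oct)
    curve = predict_response(p, p.theta_pref, p.sf_pref, tf_grid)
    fit.fwhm_tf, c = _curve_fwhm(tf_grid, curve, p.b)
    clipped |= c

    fit.tuned_sf = fit.fwhm_sf <= 6.0
    fit.tuned_tf = fit.fwhm_tf <= 6.0
    fit.fwhm_clipped = clipped
    return fit
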
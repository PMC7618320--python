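"""PSP quantification and connectivity statistics.

Covers amplitude and paired-pulse measurement from mean postsynaptic traces,
multiexponential kinetics fitting, the within-presynaptic-cell normalization
and permutation test for the reciprocal strength correlation, logistic
connection-probability models, and partial correlations controlling for
distance.  Log amplitudes are base 10 throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .synthgen import PSPTrace, psp_shape

logger = logging.getLogger(__name__)

__all__ = [
    "Connection",
    "psp_amplitude",
    "paired_pulse_ratio",
    "PSPKinetics",
    "fit_psp_kinetics",
    "reciprocal_correlation",
    "normalize_within_presyn",
    "permutation_test",
    "partial_correlation",
    "LogisticFit",
    "connection_probability_model",
    "exclusion_table",
    "category_percentages",
    "percent_variance_from_correlation",
    "SLOW_DECAY_CUTOFF_MS",
    "MAX_AMPLITUDE_TRIALS",
]

#: Pairs with decay time constants above this are excluded from strength analyses.
SLOW_DECAY_CUTOFF_MS = 25.0

#: Amplitude estimation uses at most this many initial trials.
MAX_AMPLITUDE_TRIALS = 20


@dataclass
class Connection:
    """One directed synaptic measurement between a PV+ and a pyramidal cell."""

    pre_id: int
    post_id: int
    direction: str            # 'PV->Pyr' | 'Pyr->PV'
    connected: bool
    amplitude_mv: float | None
    tau_r_ms: float | None = None
    tau_d_ms: float | None = None
    p_shape: float | None = None
    ppr: float | None = None
    distance_um: float = np.nan
    n_trials: int = 20

    @property
    def log10_amplitude(self) -> float:
        if not self.connected or self.amplitude_mv is None:
            raise ValueError("unconnected pair carries no amplitude")
        return float(np.log10(self.amplitude_mv))


def _mean_trace(traces: np.ndarray, max_trials: int = MAX_AMPLITUDE_TRIALS) -> np.ndarray:
    traces = np.atleast_2d(np.asarray(traces, float))
    return traces[:max_trials].mean(axis=0)


def psp_amplitude(
    trace: PSPTrace,
    second_psp_onset_ms: float | None = None,
    trials: np.ndarray | None = None,
) -> float:
    """Baseline-subtracted extremum of the mean postsynaptic trace (mV).

    Baseline is the mean membrane potential in the 5 ms preceding the first
    presynaptic spike.  EPSP amplitude is the post-spike maximum, IPSP the
    magnitude of the minimum.  When PSPs overlap, ``second_psp_onset_ms``
    restricts the search window to before the second response.  If ``trials``
    (n_trials, n_samples) is given, at most the first 20 are averaged first.
    """
    v = _mean_trace(trials) if trials is not None else trace.voltage_mv
    t = trace.time_ms
    spike = trace.presyn_spike_times_ms[0]
    base_mask = (t >= spike - trace.baseline_window_ms) & (t < spike)
    baseline = v[base_mask].mean() if base_mask.any() else 0.0
    hi = second_psp_onset_ms if second_psp_onset_ms is not None else np.inf
    win = (t >= spike) & (t < hi)
    if not win.any():
        raise ValueError("no post-spike samples in trace")
    seg = v[win] - baseline
    if trace.polarity == "IPSP":
        return float(-seg.min())
    return float(seg.max())


def paired_pulse_ratio(trace: PSPTrace) -> float:
    """Second/first PSP amplitude with per-pulse baselines.

    Requires two presynaptic spikes; traces where the first pulse evoked
    multiple presynaptic spikes are excluded upstream (flag on the trace).
    """
    if len(trace.presyn_spike_times_ms) < 2:
        raise ValueError("paired-pulse analysis needs two presynaptic spikes")
    if trace.multi_spike_first_pulse:
        raise ValueError("first pulse evoked multiple spikes; pair excluded")
    t = trace.time_ms
    v = trace.voltage_mv
    s1, s2 = trace.presyn_spike_times_ms[:2]
    sign = -1.0 if trace.polarity == "IPSP" else 1.0

    def pulse_amp(spike, hi):
        base_mask = (t >= spike - trace.baseline_window_ms) & (t < spike)
        baseline = v[base_mask].mean()
        win = (t >= spike) & (t < hi)
        return (sign * (v[win] - baseline)).max()

    a1 = pulse_amp(s1, s2)
    a2 = pulse_amp(s2, s2 + (s2 - s1))
    if a1 == 0:
        raise ValueError("zero first-pulse amplitude")
    return float(a2 / a1)


@dataclass
class PSPKinetics:
    v_max: float
    tau_r_ms: float
    tau_d_ms: float
    p: float
    sse: float
    converged: bool

    @property
    def slow_decay(self) -> bool:
        return self.tau_d_ms > SLOW_DECAY_CUTOFF_MS


def fit_psp_kinetics(
    trace: PSPTrace,
    n_restarts: int = 100,
    skip_initial_ms: float = 5.0,
    seed: int | np.random.Generator = 0,
) -> PSPKinetics:
    """Multi-start least-squares fit of V(t) = Vmax (1-e^(-t/tau_r))^p e^(-t/tau_d).

    Fits the baseline-subtracted mean response from the presynaptic spike,
    excluding the first ``skip_initial_ms`` to avoid stimulation artefacts.
    The best SSE over ``n_restarts`` seeded starts is kept.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t = trace.time_ms
    v = trace.voltage_mv
    spike = trace.presyn_spike_times_ms[0]
    base_mask = (t >= spike - trace.baseline_window_ms) & (t < spike)
    baseline = v[base_mask].mean() if base_mask.any() else 0.0
    sign = -1.0 if trace.polarity == "IPSP" else 1.0
    m = t >= spike + skip_initial_ms
    ts = t[m] - spike
    ys = sign * (v[m] - baseline)
    if ts.size < 8:
        raise ValueError("too few samples after the skipped onset")

    def resid(x):
        vm, tr, td, p = x
        return vm * psp_shape(ts, tr, td, p) - ys

    peak = max(ys.max(), 1e-6)
    lo = np.array([1e-6, 0.05, 0.5, 0.5])
    hi = np.array([50 * peak, 50.0, 500.0, 10.0])
    best = None
    for _ in range(n_restarts):
        x0 = np.array([
            peak * rng.uniform(0.5, 5.0),
            np.exp(rng.uniform(np.log(0.1), np.log(20.0))),
            np.exp(rng.uniform(np.log(1.0), np.log(200.0))),
            rng.uniform(0.5, 5.0),
        ])
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if not res.success:
            continue
        sse = float(2 * res.cost)
        if best is None or sse < best[0]:
            best = (sse, res.x)
    if best is None:
        return PSPKinetics(np.nan, np.nan, np.nan, np.nan, np.inf, False)
    sse, (vm, tr, td, p) = best
    # flag fits that explain essentially nothing (e.g. pure noise input)
    converged = sse < 0.95 * float(np.sum((ys - ys.mean()) ** 2)) + 1e-12
    return PSPKinetics(float(vm), float(tr), float(td), float(p), sse, converged)


def _reciprocal_table(connections) -> pd.DataFrame:
    """Long table of reciprocally connected pairs with both log amplitudes."""
    rows = {}
    for c in connections:
        if not c.connected or c.amplitude_mv is None:
            continue
        if c.direction == "PV->Pyr":
            key, col = (c.pre_id, c.post_id), "ipsp"
        else:
            key, col = (c.post_id, c.pre_id), "epsp"
        rows.setdefault(key, {})[col] = c.amplitude_mv
    recs = [
        {"pv_id": pv, "pyr_id": py,
         "log_ipsp": np.log10(d["ipsp"]), "log_epsp": np.log10(d["epsp"])}
        for (pv, py), d in rows.items() if "ipsp" in d and "epsp" in d
    ]
    return pd.DataFrame(recs, columns=["pv_id", "pyr_id", "log_ipsp", "log_epsp"])


def reciprocal_correlation(connections) -> tuple[float, float, int]:
    """Pearson correlation of log10 EPSP vs log10 IPSP over reciprocal pairs."""
    tab = _reciprocal_table(connections)
    if len(tab) < 3:
        raise ValueError(f"need >= 3 reciprocal pairs, got {len(tab)}")
    r, p = stats.pearsonr(tab["log_epsp"], tab["log_ipsp"])
    return float(r), float(p), len(tab)


def normalize_within_presyn(
    connections,
    mean_kind: str = "geometric",
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Per-PV-cell normalized reciprocal strengths (slice-quality control).

    Only PV cells with reciprocal connections to at least 2 pyramidal cells
    enter.  Each log10 amplitude is divided by the cell's mean log10
    amplitude of the same polarity (the geometric-mean normalization written
    as a ratio of logs).  ``mean_kind='arithmetic'`` divides by the log10 of
    the arithmetic-mean amplitude instead.  Cells whose mean log lies within
    ``eps`` of 0 are excluded with a warning (the ratio blows up there).
    """
    tab = _reciprocal_table(connections)
    out = []
    for pv, grp in tab.groupby("pv_id"):
        if len(grp) < 2:
            continue
        if mean_kind == "geometric":
            mi = grp["log_ipsp"].mean()
            me = grp["log_epsp"].mean()
        elif mean_kind == "arithmetic":
            mi = np.log10(np.mean(10.0 ** grp["log_ipsp"]))
            me = np.log10(np.mean(10.0 ** grp["log_epsp"]))
        else:
            raise ValueError(f"unknown mean_kind {mean_kind!r}")
        if abs(mi) < eps or abs(me) < eps:
            warnings.warn(f"PV cell {pv}: mean log amplitude ~ 0, excluded "
                          "from normalization")
            continue
        g = grp.copy()
        g["ipsp_norm"] = g["log_ipsp"] / mi
        g["epsp_norm"] = g["log_epsp"] / me
        out.append(g)
    if not out:
        return pd.DataFrame(columns=["pv_id", "pyr_id", "log_ipsp", "log_epsp",
                                     "ipsp_norm", "epsp_norm"])
    return pd.concat(out, ignore_index=True)


def permutation_test(
    normalized: pd.DataFrame,
    n_shuffles: int = 10000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Within-PV-cell permutation test of the normalized E/I correlation.

    The observed statistic is the pooled Pearson correlation of normalized
    IPSP vs EPSP values.  IPSP values are permuted within each PV cell only;
    the p value is the exact proportion of shuffles whose |R| meets or
    exceeds the observed |R| (ties count as exceedances, no smoothing).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    x = normalized["epsp_norm"].to_numpy(float)
    y = normalized["ipsp_norm"].to_numpy(float)
    groups = normalized["pv_id"].to_numpy()
    sizes = pd.Series(groups).value_counts()
    if (sizes < 2).all() or len(sizes) < 2:
        raise ValueError("need >= 2 PV cells with >= 2 pairs each for shuffling")

    r_obs = float(np.corrcoef(x, y)[0, 1])

    # vectorized within-group shuffles: argsort of random keys per group
    y_shuf = np.tile(y, (n_shuffles, 1))
    for g in sizes.index:
        idx = np.where(groups == g)[0]
        if idx.size < 2:
            continue
        keys = rng.random((n_shuffles, idx.size))
        perm = np.argsort(keys, axis=1)
        y_shuf[:, idx] = y[idx][perm]

    xc = x - x.mean()
    yc = y_shuf - y_shuf.mean(axis=1, keepdims=True)
    num = yc @ xc
    den = np.sqrt((yc ** 2).sum(axis=1) * (xc ** 2).sum())
    r_shuf = num / den
    p = float(np.mean(np.abs(r_shuf) >= abs(r_obs)))
    return r_obs, p


def partial_correlation(x, y, covariate) -> tuple[float, float]:
    """Pearson correlation of residuals after regressing both on a covariate."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    c = np.asarray(covariate, float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.std(c) == 0:
        logger.warning("constant covariate; partial correlation reduces to "
                       "plain Pearson")
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)
    design = np.column_stack([c, np.ones_like(c)])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if np.std(rx) < 1e-12 * max(np.std(x), 1.0) or \
       np.std(ry) < 1e-12 * max(np.std(y), 1.0):
        raise ValueError("residuals are degenerate; partial correlation undefined")
    r, p = stats.pearsonr(rx, ry)
    return float(r), float(p)


@dataclass
class LogisticFit:
    intercept: float
    slope: float
    slope_se: float
    p_value: float
    separated: bool
    n_iter: int


def connection_probability_model(
    similarity: np.ndarray,
    connected: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> LogisticFit:
    """Logistic regression of connection probability on response similarity.

    Maximum-likelihood fit by iteratively reweighted least squares with a
    complete-separation detector; the p value is the two-sided Wald test of
    the slope.  On separation the fit is flagged and p is NaN.
    """
    s = np.asarray(similarity, float)
    yv = np.asarray(connected, float)
    if set(np.unique(yv)) - {0.0, 1.0}:
        raise ValueError("connected flags must be binary")
    if yv.min() == yv.max():
        raise ValueError("need both connected and unconnected pairs")
    X = np.column_stack([np.ones_like(s), s])
    beta = np.zeros(2)
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = mu * (1 - mu)
        if w.max() < 1e-10 or np.abs(beta).max() > 1e3:
            separated = True
            break
        z = eta + (yv - mu) / np.maximum(w, 1e-12)
        wx = X * w[:, None]
        new = np.linalg.solve(X.T @ wx, wx.T @ z)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    # separation heuristic: fitted probabilities hug 0/1 on both classes
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    if np.all((mu > 1 - 1e-6) == (yv == 1)) and np.all(np.abs(mu - yv) < 1e-6):
        separated = True
    if separated:
        return LogisticFit(float(beta[0]), float(beta[1]), np.nan, np.nan, True, it)
    w = mu * (1 - mu)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = float(np.sqrt(cov[1, 1]))
    zstat = beta[1] / se
    p = float(2 * stats.norm.sf(abs(zstat)))
    return LogisticFit(float(beta[0]), float(beta[1]), se, p, False, it)


def exclusion_table(
    connections,
    pair_keep: dict[tuple[int, int], bool] | None = None,
    responsive_pyr: set[int] | None = None,
    tau_d_cutoff_ms: float = SLOW_DECAY_CUTOFF_MS,
    max_trials: int = MAX_AMPLITUDE_TRIALS,
) -> pd.DataFrame:
    """Per-connection record of every exclusion rule applied.

    Columns flag the four gates: amplitude restricted to the first
    ``max_trials`` trials, slow decay (tau_d above the cutoff), the
    close-pair (10 um / adjacent plane) rule via ``pair_keep``, and the
    pyramidal-cell responsiveness gate.  ``kept`` is True when the
    connection survives all strength-analysis filters.
    """
    rows = []
    for c in connections:
        pv, py = ((c.pre_id, c.post_id) if c.direction == "PV->Pyr"
                  else (c.post_id, c.pre_id))
        trials_capped = c.n_trials > max_trials
        slow = (c.tau_d_ms is not None) and (c.tau_d_ms > tau_d_cutoff_ms)
        too_close = (pair_keep is not None
                     and not pair_keep.get((pv, py), True))
        unresponsive = (responsive_pyr is not None
                        and py not in responsive_pyr)
        rows.append({
            "pv_id": pv, "pyr_id": py, "direction": c.direction,
            "connected": c.connected,
            "trials_capped_at_20": trials_capped,
            "slow_decay_excluded": slow,
            "close_pair_excluded": too_close,
            "unresponsive_excluded": unresponsive,
            "kept": c.connected and not (slow or too_close or unresponsive),
        })
    return pd.DataFrame(rows)


def category_percentages(
    counts: dict[str, int] | tuple[int, int, int, int],
) -> dict[str, float]:
    """Connection-category percentages (nearest percent) from probed-pair counts.

    Categories order as (bidirectional, inhibitory_only, excitatory_only,
    unconnected).
    """
    if isinstance(counts, dict):
        names = ("bidirectional", "inhibitory_only", "excitatory_only", "unconnected")
        vals = [counts[n] for n in names]
    else:
        names = ("bidirectional", "inhibitory_only", "excitatory_only", "unconnected")
        vals = list(counts)
    total = sum(vals)
    if total == 0:
        return {n: np.nan for n in names} | {"n": 0}
    out = {n: round(100.0 * v / total) for n, v in zip(names, vals)}
    out["n"] = total
    return out


def percent_variance_from_correlation(r: float) -> int:
    """Variance explained by a correlate, as a whole percentage: round(100 r^2)."""
    return round(100.0 * r * r)
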
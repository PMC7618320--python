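"""Stimulation protocols: tuned input, stimulus battery, cohort perturbation."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .build import NetworkModel
from .config import NetworkConfig
from .simulate import CurrentStep, SimResult, simulate

logger = logging.getLogger(__name__)

__all__ = [
    "tuned_input",
    "battery_stimuli",
    "run_stimulus_battery",
    "run_stability_protocol",
    "perturb_cohort",
    "select_cohort",
    "calibrate_background",
    "BatteryResult",
    "PerturbResult",
]


def tuned_input(
    prefs: np.ndarray,
    n_e: int,
    gamma_stim: np.ndarray,
    kappa: float,
    max_current_pa: float = 12.0,
) -> np.ndarray:
    """Per-neuron stimulus currents for one stimulus (pA).

    u_i = prod_d phi(gamma_i^d, gamma_stim^d, kappa), min-max normalized over
    the excitatory population and scaled to ``max_current_pa``.  Only
    excitatory neurons are driven; inhibitory preference emerges from their
    connectivity with excitatory cells.
    """
    gamma_stim = np.asarray(gamma_stim, float)
    u = np.exp(kappa * np.cos(prefs[:n_e] - gamma_stim[None, :]).sum(axis=1))
    rng_u = u.max() - u.min()
    out = np.zeros(prefs.shape[0])
    if rng_u == 0:
        logger.warning("degenerate tuned input (max = min); zero current applied")
        return out
    out[:n_e] = max_current_pa * (u - u.min()) / rng_u
    return out


def battery_stimuli(d: int = 2, step: float = np.pi / 2) -> np.ndarray:
    """Stimulus grid spanning all tuning dimensions in increments of ``step``."""
    axis = np.arange(-np.pi, np.pi, step)
    grids = np.meshgrid(*([axis] * d), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


@dataclass
class BatteryResult:
    sim: SimResult
    stimuli: np.ndarray          # (n_stim, D)
    stim_rates: np.ndarray       # (n_neurons, n_stim) mean rate during stimulus
    binned_rates: np.ndarray     # (n_neurons, n_bins) at bin_ms
    bin_ms: float
    on_ms: float
    period_ms: float


def run_stimulus_battery(
    model: NetworkModel,
    on_ms: float = 400.0,
    period_ms: float = 1000.0,
    bin_ms: float = 250.0,
    seed=0,
    probe_ids: np.ndarray | None = None,
    stimuli: np.ndarray | None = None,
) -> BatteryResult:
    """Present the stimulus battery (default 16 stimuli, pi/2 increments).

    Each stimulus is a 400 ms tuned current at 1 Hz; rates are returned both
    per stimulus window and in fixed 250 ms bins for similarity analyses.
    """
    cfg = model.config
    if stimuli is None:
        stimuli = battery_stimuli(cfg.d)
    steps = []
    for k, g in enumerate(stimuli):
        cur = tuned_input(model.prefs, cfg.n_e, g, cfg.k_ee, cfg.stim_max_pa)
        steps.append(CurrentStep(k * period_ms, k * period_ms + on_ms, cur))
    duration = len(stimuli) * period_ms
    sim = simulate(model, duration, steps, seed=seed, probe_ids=probe_ids)
    stim_rates = np.stack(
        [sim.rates(k * period_ms, k * period_ms + on_ms) for k in range(len(stimuli))],
        axis=1,
    )
    return BatteryResult(sim, stimuli, stim_rates, sim.binned_rates(bin_ms),
                         bin_ms, on_ms, period_ms)


def run_stability_protocol(
    model: NetworkModel,
    n_cycles: int = 4,
    on_ms: float = 400.0,
    period_ms: float = 1000.0,
    gamma_stim: np.ndarray | None = None,
    seed=0,
) -> tuple[SimResult, list[tuple[float, float]], list[tuple[float, float]]]:
    """Repeated tuned stimulation with off periods, for stability analysis.

    Returns the simulation plus the on windows and off windows (ms).
    """
    cfg = model.config
    if gamma_stim is None:
        gamma_stim = np.zeros(cfg.d)
    cur = tuned_input(model.prefs, cfg.n_e, gamma_stim, cfg.k_ee, cfg.stim_max_pa)
    steps = [CurrentStep(k * period_ms, k * period_ms + on_ms, cur)
             for k in range(n_cycles)]
    sim = simulate(model, n_cycles * period_ms, steps, seed=seed)
    on = [(k * period_ms, k * period_ms + on_ms) for k in range(n_cycles)]
    off = [(k * period_ms + on_ms, (k + 1) * period_ms) for k in range(n_cycles)]
    return sim, on, off


def select_cohort(
    model: NetworkModel,
    size: int = 11,
    gamma_target: np.ndarray | None = None,
    tol_feature2: float = np.pi / 16,
) -> np.ndarray:
    """Excitatory cohort for the perturbation protocol.

    The cohort comprises the ``size`` excitatory neurons nearest the target
    in the first tuning dimension among those whose second-dimension
    preference lies within ``tol_feature2`` of the target.
    """
    cfg = model.config
    if gamma_target is None:
        gamma_target = np.zeros(cfg.d)
    pe = model.prefs[: cfg.n_e]

    def circ_dist(a, b):
        return np.abs(np.angle(np.exp(1j * (a - b))))

    d2 = circ_dist(pe[:, 1], gamma_target[1]) if cfg.d > 1 else np.zeros(len(pe))
    eligible = np.where(d2 <= tol_feature2)[0]
    if eligible.size < size:
        raise ValueError(
            f"only {eligible.size} excitatory neurons within tolerance "
            f"{tol_feature2:.4f} of the feature-2 target; need {size}")
    d1 = circ_dist(pe[eligible, 0], gamma_target[0])
    return eligible[np.argsort(d1)[:size]]


@dataclass
class PerturbResult:
    sim: SimResult
    cohort: np.ndarray
    pre_rates: np.ndarray     # (n_neurons,) Hz, window before each injection
    post_rates: np.ndarray    # (n_neurons,) Hz, window after injection onset
    gamma_target: np.ndarray

    def summary(self) -> dict:
        n_e = self.sim.n_e
        is_cohort = np.zeros(self.sim.n, bool)
        is_cohort[self.cohort] = True
        e_mask = np.arange(self.sim.n) < n_e
        delta = self.post_rates - self.pre_rates
        i_mask = ~e_mask
        noncohort_e = e_mask & ~is_cohort
        return {
            "cohort_size": int(self.cohort.size),
            "frac_i_facilitated": float(np.mean(delta[i_mask] > 0)),
            "frac_noncohort_e_suppressed": float(np.mean(delta[noncohort_e] < 0)),
            "frac_noncohort_e_facilitated": float(np.mean(delta[noncohort_e] > 0)),
            "cohort_delta_hz": float(delta[is_cohort].mean()),
        }


def perturb_cohort(
    model: NetworkModel,
    cohort_size: int = 11,
    gamma_target: np.ndarray | None = None,
    tol_feature2: float = np.pi / 16,
    current_pa: float = 200e3,  # 200 nA
    pulse_ms: float = 10.0,
    pulse_rate_hz: float = 10.0,
    n_pulses: int = 10,
    bg_rate_hz: float = 3500.0,
    settle_ms: float = 200.0,
    pre_window_ms: float = 20.0,
    post_window_ms: float = 50.0,
    seed=0,
) -> PerturbResult:
    """Stimulate a co-tuned excitatory cohort and measure network effects.

    Background drive is raised to ``bg_rate_hz``; the cohort receives
    current pulses (200 nA, 10 ms, 10 Hz by default).  Per-neuron rates are
    measured in the 20 ms preceding each injection and the 50 ms following
    its onset, averaged over pulses.
    """
    cfg = model.config
    if gamma_target is None:
        gamma_target = np.zeros(cfg.d)
    cohort = select_cohort(model, cohort_size, gamma_target, tol_feature2)
    cur = np.zeros(cfg.n)
    cur[cohort] = current_pa
    period = 1000.0 / pulse_rate_hz
    onsets = [settle_ms + k * period for k in range(n_pulses)]
    steps = [CurrentStep(t0, t0 + pulse_ms, cur) for t0 in onsets]
    duration = settle_ms + n_pulses * period
    sim = simulate(model, duration, steps, bg_rate_hz=bg_rate_hz, seed=seed)

    pre = np.zeros(cfg.n)
    post = np.zeros(cfg.n)
    for t0 in onsets:
        pre += sim.rates(t0 - pre_window_ms, t0)
        post += sim.rates(t0, t0 + post_window_ms)
    pre /= n_pulses
    post /= n_pulses
    return PerturbResult(sim, cohort, pre, post, np.asarray(gamma_target, float))


def calibrate_background(
    config: NetworkConfig,
    target_rate_hz: float = 2.0,
    n_neurons: int = 200,
    sim_ms: float = 1000.0,
    tol_hz: float = 0.25,
    max_iter: int = 20,
    seed=0,
) -> float:
    """Bisection on the background weight to hit a spontaneous target rate.

    Simulates an unconnected population (W = 0) under the Poisson barrage
    alone; returns the calibrated ``bg_weight_ns``.
    """
    from dataclasses import replace
    from .build import NetworkModel as NM

    base = replace(config, n=n_neurons, s_e=0.0, s_i=0.0)
    prefs = np.zeros((n_neurons, config.d))
    w0 = np.zeros((n_neurons, n_neurons))

    def rate(bw):
        cfg = replace(base, bg_weight_ns=bw)
        m = NM(cfg, prefs, w0)
        sim = simulate(m, sim_ms, seed=seed)
        return sim.rates().mean()

    lo, hi = 0.01, 5.0
    while rate(hi) < target_rate_hz and hi < 50:
        hi *= 2
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r = rate(mid)
        if abs(r - target_rate_hz) <= tol_hz:
            return float(mid)
        if r < target_rate_hz:
            lo = mid
        else:
            hi = mid
    return float(0.5 * (lo + hi))
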
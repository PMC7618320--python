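"""Analyses of simulation results: stability, conductance co-tuning, selectivity."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import SimResult
from .protocols import BatteryResult
from ..tuning import selectivity_skewness

__all__ = ["stability_index", "conductance_cotuning", "population_selectivity",
           "StabilityResult", "CotuningResult"]


@dataclass
class StabilityResult:
    ratios: list[float]
    index: float
    label: str  # 'stable' | 'unstable'

    @property
    def stable(self) -> bool:
        return self.label == "stable"


def stability_index(
    sim: SimResult,
    on_windows: list[tuple[float, float]],
    off_windows: list[tuple[float, float]],
    tail_ms: float = 200.0,
    threshold: float = 0.5,
) -> StabilityResult:
    """Persistence of excitatory activity after stimulus offset.

    For each cycle, the ratio of the population E rate in the last
    ``tail_ms`` of the off period to the rate during stimulation.  The
    network is labelled unstable when the ratio exceeds ``threshold`` in a
    majority of cycles (activity persisting without external input).
    """
    if not off_windows:
        raise ValueError("protocol has no off periods")
    e_ids = np.arange(sim.n_e)
    ratios = []
    for (a_on, b_on), (a_off, b_off) in zip(on_windows, off_windows):
        r_on = sim.rates(a_on, b_on)[e_ids].mean()
        r_off = sim.rates(max(b_off - tail_ms, a_off), b_off)[e_ids].mean()
        if r_on == 0:
            ratios.append(0.0 if r_off == 0 else np.inf)
        else:
            ratios.append(float(r_off / r_on))
    idx = float(np.median(ratios))
    unstable = np.mean([r > threshold for r in ratios]) > 0.5
    return StabilityResult(ratios, idx, "unstable" if unstable else "stable")


@dataclass
class CotuningResult:
    probe_ids: np.ndarray
    correlations: np.ndarray          # per-probe Pearson(g_E(t), g_I(t))
    g_e_tuning: np.ndarray | None     # (n_probe, n_stim) stimulus-mean g_E
    g_i_tuning: np.ndarray | None

    @property
    def median_correlation(self) -> float:
        valid = self.correlations[np.isfinite(self.correlations)]
        return float(np.median(valid)) if valid.size else np.nan


def conductance_cotuning(
    result: SimResult | BatteryResult,
) -> CotuningResult:
    """Correlation and tuning of excitatory vs inhibitory input conductances.

    Per probed neuron, the Pearson correlation of g_E(t) and g_I(t) at the
    recorded (0.1 ms) resolution over the whole simulation; for battery
    results, additionally the stimulus-averaged conductance tuning curves.
    Constant conductances give NaN and are excluded from the median.
    """
    if isinstance(result, BatteryResult):
        sim = result.sim
    else:
        sim = result
    if sim.g_e_probe is None:
        raise ValueError("no conductance probes were recorded")
    ge, gi = sim.g_e_probe, sim.g_i_probe
    corr = np.full(ge.shape[0], np.nan)
    for k in range(ge.shape[0]):
        if ge[k].std() > 0 and gi[k].std() > 0:
            corr[k] = np.corrcoef(ge[k], gi[k])[0, 1]

    g_e_tune = g_i_tune = None
    if isinstance(result, BatteryResult):
        n_stim = len(result.stimuli)
        steps_per_ms = 1.0 / sim.dt_ms
        g_e_tune = np.empty((ge.shape[0], n_stim))
        g_i_tune = np.empty((ge.shape[0], n_stim))
        for k in range(n_stim):
            a = int(k * result.period_ms * steps_per_ms)
            b = int((k * result.period_ms + result.on_ms) * steps_per_ms)
            g_e_tune[:, k] = ge[:, a:b].mean(axis=1)
            g_i_tune[:, k] = gi[:, a:b].mean(axis=1)
    return CotuningResult(sim.probe_ids, corr, g_e_tune, g_i_tune)


def population_selectivity(battery: BatteryResult) -> tuple[np.ndarray, np.ndarray]:
    """Selectivity skewness of per-stimulus rates for E and I populations.

    Returns (skewness of E cells, skewness of I cells); cells with zero
    rate variance across stimuli are dropped.
    """
    rates = battery.stim_rates
    n_e = battery.sim.n_e

    def skews(block):
        out = []
        for row in block:
            if row.std() > 0:
                out.append(selectivity_skewness(row))
        return np.asarray(out)

    return skews(rates[:n_e]), skews(rates[n_e:])
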
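"""Fixed-step LIF integration with alpha-function conductance synapses.

Exponential-Euler updates throughout: the two-state alpha synapse
(g' = -g/tau + h, h' = -h/tau) is advanced exactly each step, and the
membrane equation is integrated against the instantaneous total conductance.
A presynaptic spike with weight w produces a conductance transient peaking
at exactly w one synaptic time constant after arrival.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .build import NetworkModel

__all__ = ["CurrentStep", "SimResult", "simulate"]


@dataclass(frozen=True)
class CurrentStep:
    """Constant per-neuron current injection over [t_start, t_stop) ms."""

    t_start_ms: float
    t_stop_ms: float
    current_pa: np.ndarray  # (N,) pA


@dataclass
class SimResult:
    """Spikes, optional conductance probes, and the stimulus schedule."""

    spike_times_ms: np.ndarray
    spike_ids: np.ndarray
    duration_ms: float
    n: int
    n_e: int
    probe_ids: np.ndarray | None = None
    g_e_probe: np.ndarray | None = None   # (n_probe, n_steps) nS
    g_i_probe: np.ndarray | None = None
    dt_ms: float = 0.1
    schedule: list = field(default_factory=list)

    def rates(self, t_start_ms: float = 0.0, t_stop_ms: float | None = None) -> np.ndarray:
        """Mean firing rate (Hz) per neuron in a window."""
        t1 = self.duration_ms if t_stop_ms is None else t_stop_ms
        m = (self.spike_times_ms >= t_start_ms) & (self.spike_times_ms < t1)
        counts = np.bincount(self.spike_ids[m], minlength=self.n)
        return counts / ((t1 - t_start_ms) / 1000.0)

    def binned_rates(self, bin_ms: float = 250.0) -> np.ndarray:
        """(n_neurons, n_bins) firing rates in fixed bins (Hz)."""
        n_bins = int(np.floor(self.duration_ms / bin_ms))
        edges = np.arange(n_bins + 1) * bin_ms
        m = self.spike_times_ms < edges[-1]
        b = np.floor(self.spike_times_ms[m] / bin_ms).astype(int)
        out = np.zeros((self.n, n_bins))
        np.add.at(out, (self.spike_ids[m], b), 1.0)
        return out / (bin_ms / 1000.0)


def simulate(
    model: NetworkModel,
    duration_ms: float,
    currents: list[CurrentStep] | None = None,
    bg_rate_hz: float | None = None,
    seed=0,
    probe_ids: np.ndarray | None = None,
    record_every: int = 1,
) -> SimResult:
    """Run the network for ``duration_ms`` under a current-step protocol.

    Each neuron receives an independent Poisson barrage of excitatory input
    events at ``bg_rate_hz`` (config default) with peak conductance
    ``bg_weight_ns``.  Recurrent spikes are delivered after the synaptic
    delay with per-pair weights from the signed matrix.  Deterministic given
    ``seed``.  Conductances of ``probe_ids`` are recorded every
    ``record_every`` steps.
    """
    cfg = model.config
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = cfg.n
    dt = cfg.dt_ms
    n_steps = int(round(duration_ms / dt))
    bg_rate = cfg.bg_rate_hz if bg_rate_hz is None else bg_rate_hz

    w = model.weights
    w_exc = np.clip(w, 0.0, None)
    w_inh = np.clip(-w, 0.0, None)

    # decay factors
    de = np.exp(-dt / cfg.tau_syn_e_ms)
    di = np.exp(-dt / cfg.tau_syn_i_ms)
    ke = np.e / cfg.tau_syn_e_ms  # h increment per unit weight -> peak g = w
    ki = np.e / cfg.tau_syn_i_ms
    delay_steps = max(int(round(cfg.delay_ms / dt)), 1)
    ref_steps = int(round(cfg.t_ref_ms / dt))
    p_bg = bg_rate * dt * 1e-3  # expected background events per step

    v = np.full(n, cfg.e_l_mv)
    ge = np.zeros(n)
    he = np.zeros(n)
    gi = np.zeros(n)
    hi = np.zeros(n)
    refr = np.zeros(n, int)
    ring: list[np.ndarray] = [np.empty(0, int) for _ in range(delay_steps)]

    # current schedule compiled to step indices
    steps_sched = []
    for c in currents or []:
        steps_sched.append((int(round(c.t_start_ms / dt)),
                            int(round(c.t_stop_ms / dt)),
                            np.asarray(c.current_pa, float)))

    spike_t: list[np.ndarray] = []
    spike_i: list[np.ndarray] = []
    do_probe = probe_ids is not None
    if do_probe:
        probe_ids = np.asarray(probe_ids, int)
        n_rec = (n_steps + record_every - 1) // record_every
        g_e_rec = np.empty((len(probe_ids), n_rec))
        g_i_rec = np.empty((len(probe_ids), n_rec))

    gl, el, eex, ein, cm = cfg.g_l_ns, cfg.e_l_mv, cfg.e_ex_mv, cfg.e_in_mv, cfg.c_m_pf
    vth, vres = cfg.v_th_mv, cfg.v_reset_mv

    for t in range(n_steps):
        # deliver delayed recurrent spikes
        spk = ring[t % delay_steps]
        if spk.size:
            he += ke * w_exc[:, spk].sum(axis=1)
            hi += ki * w_inh[:, spk].sum(axis=1)
        # background barrage
        if p_bg > 0:
            he += (ke * cfg.bg_weight_ns) * rng.poisson(p_bg, n)
        # exact alpha-synapse update
        ge = (ge + dt * he) * de
        he = he * de
        gi = (gi + dt * hi) * di
        hi = hi * di
        if do_probe and t % record_every == 0:
            g_e_rec[:, t // record_every] = ge[probe_ids]
            g_i_rec[:, t // record_every] = gi[probe_ids]
        # injected currents
        i_ext = 0.0
        for a, b, cur in steps_sched:
            if a <= t < b:
                i_ext = i_ext + cur
        # membrane update (exponential Euler against total conductance)
        gtot = gl + ge + gi
        vinf = (gl * el + ge * eex + gi * ein + i_ext) / gtot
        lam = np.exp(-dt * gtot / cm)
        v = vinf + (v - vinf) * lam
        # refractory clamp
        in_ref = refr > 0
        v[in_ref] = vres
        refr[in_ref] -= 1
        # threshold crossing
        fired = np.where(v >= vth)[0]
        if fired.size:
            v[fired] = vres
            refr[fired] = ref_steps
            spike_t.append(np.full(fired.size, (t + 1) * dt))
            spike_i.append(fired)
        ring[t % delay_steps] = fired

    times = np.concatenate(spike_t) if spike_t else np.empty(0)
    ids = np.concatenate(spike_i) if spike_i else np.empty(0, int)
    res = SimResult(times, ids, duration_ms, n, cfg.n_e, dt_ms=dt,
                    schedule=list(steps_sched))
    if do_probe:
        res.probe_ids = probe_ids
        res.g_e_probe = g_e_rec
        res.g_i_probe = g_i_rec
    return res
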
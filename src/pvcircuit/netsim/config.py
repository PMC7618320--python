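"""Configuration of the structured E/I spiking network."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["NetworkConfig", "reference_config"]


@dataclass
class NetworkConfig:
    """All network, neuron, and synapse parameters.

    Connectivity parameters follow the model's parameter table (N, wE, wI,
    fE, fI, dIE, sE, sI, kappa blocks, D, fill factors).  Neuron and synapse
    constants are standard leaky integrate-and-fire with alpha-function
    conductance synapses; they are not dictated by the connectivity model and
    are fully exposed here.  Weights are conductance amplitudes in nS.
    """

    # --- connectivity ---
    n: int = 5000
    f_i: float = 0.2
    w_e: float = 45.0          # total output conductance of one E cell, nS
    w_i: float = 450.0         # total output conductance of one I cell, nS
    d_ie: float = 2.0          # E->I weights are d_ie times stronger
    s_e: float = 0.0           # excitatory specificity in [0, 1]
    s_i: float = 0.0           # inhibitory specificity in [-1, 1]
    k_ee: float = 4.0
    k_ei: float = 0.5
    k_ie: float = 0.5
    k_ii: float = 0.5
    d: int = 2                 # number of tuning dimensions
    h_e: float = 1.0           # synaptic fill factors (dense)
    h_i: float = 1.0

    # --- neuron (LIF) ---
    c_m_pf: float = 250.0
    g_l_ns: float = 25.0       # tau_m = 10 ms
    e_l_mv: float = -70.0
    v_th_mv: float = -55.0
    v_reset_mv: float = -70.0
    t_ref_ms: float = 2.0
    e_ex_mv: float = 0.0
    e_in_mv: float = -85.0

    # --- synapse (alpha conductance) ---
    tau_syn_e_ms: float = 0.5
    tau_syn_i_ms: float = 1.0
    delay_ms: float = 1.0

    # --- background / input ---
    bg_rate_hz: float = 2400.0
    bg_weight_ns: float = 1.1  # per-event peak conductance of background input
    stim_max_pa: float = 12.0

    # --- integration ---
    dt_ms: float = 0.1
    seed: int = 0

    @property
    def f_e(self) -> float:
        return 1.0 - self.f_i

    @property
    def n_e(self) -> int:
        return int(round(self.n * self.f_e))

    @property
    def n_i(self) -> int:
        return self.n - self.n_e

    def __post_init__(self):
        if not 0.0 < self.f_i < 1.0:
            raise ValueError("f_i must lie in (0, 1)")
        if self.w_e <= 0 or self.w_i <= 0:
            raise ValueError("w_e and w_i must be positive")
        if self.d_ie < 1:
            raise ValueError("d_ie must be >= 1")
        if not 0.0 <= self.s_e <= 1.0:
            raise ValueError("s_e must lie in [0, 1]")
        if not -1.0 <= self.s_i <= 1.0:
            raise ValueError("s_i must lie in [-1, 1]")
        for k in ("k_ee", "k_ei", "k_ie", "k_ii"):
            if getattr(self, k) < 0:
                raise ValueError(f"{k} must be >= 0")
        # dt stability guard against the fastest synaptic time constant
        if self.dt_ms > min(self.tau_syn_e_ms, self.tau_syn_i_ms):
            raise ValueError("dt exceeds the fastest synaptic time constant")

    def kappa(self, target: str, source: str) -> float:
        return {"ee": self.k_ee, "ei": self.k_ei,
                "ie": self.k_ie, "ii": self.k_ii}[target + source]

    # -- YAML round trip; table-style keys --
    _YAML_KEYS = {
        "N": "n", "wE": "w_e", "wI": "w_i", "fI": "f_i", "dIE": "d_ie",
        "sE": "s_e", "sI": "s_i", "kEE": "k_ee", "kEI": "k_ei",
        "kIE": "k_ie", "kII": "k_ii", "D": "d",
    }

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        out = {}
        inv = {v: k for k, v in self._YAML_KEYS.items()}
        for key, val in d.items():
            out[inv.get(key, key)] = val
        out["fE"] = self.f_e
        Path(path).write_text(yaml.safe_dump(out, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NetworkConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.pop("fE", None)
        kwargs = {}
        for key, val in raw.items():
            kwargs[cls._YAML_KEYS.get(key, key)] = val
        return cls(**kwargs)


#: Calibrated operating points for scaled-down networks.  Weights are
#: re-calibrated per network size so the specificity regime boundaries
#: (uniform stable / specific-E unstable / +specific-I stable / lateral-I
#: unstable) survive the scale reduction; stimulus current is raised so the
#: evoked response is resolvable against the spontaneous floor at small N.
_SCALED_PRESETS = {
    1500: dict(w_e=2400.0, w_i=9000.0, bg_weight_ns=1.32, stim_max_pa=100.0),
    1000: dict(w_e=1600.0, w_i=6000.0, bg_weight_ns=1.32, stim_max_pa=100.0),
    500: dict(w_e=800.0, w_i=8000.0, bg_weight_ns=1.41, stim_max_pa=100.0),
}


def reference_config(n: int = 5000, **overrides) -> NetworkConfig:
    """Configuration with weights re-calibrated for network size.

    For the calibrated sizes (500, 1000, 1500) the preset weights, background
    weight, and stimulus scale are applied; other sizes interpolate the
    per-neuron output weight linearly in n.  Any keyword overrides win.
    """
    cfg: dict = dict(n=n)
    if n in _SCALED_PRESETS:
        cfg.update(_SCALED_PRESETS[n])
    elif n < 5000:
        cfg.update(w_e=1.6 * n, w_i=6.0 * n, bg_weight_ns=1.32,
                   stim_max_pa=100.0)
    cfg.update(overrides)
    return NetworkConfig(**cfg)
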
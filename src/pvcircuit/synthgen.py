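"""Seeded synthetic datasets with the statistical structure the analysis assumes.

Generates ground-truth tuned cells, trial-resolved dF/F tensors, and directed
PV/pyramidal synaptic measurements with configurable similarity-strength
coupling, standing in for the deposited experimental data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import StimulusEnsemble, default_ensemble
from .tuning import TuningParams, predict_response, stimulus_means
from .similarity import response_similarity

__all__ = [
    "ClassProfile",
    "GroundTruthCell",
    "TrialTensor",
    "ConnectivityParams",
    "SyntheticPairedDataset",
    "gen_cells",
    "gen_trials",
    "gen_connections",
    "gen_psp_trace",
    "gen_paired_pulse_trace",
    "gen_dataset",
    "psp_shape",
    "psp_peak_time",
]

PV = "PV+"
PYR = "PV-"

#: The four connection categories of a pair probed in both directions.
CATEGORIES = ("bidirectional", "inhibitory_only", "excitatory_only", "unconnected")


@dataclass
class ClassProfile:
    """Uniform sampling ranges for ground-truth tuning parameters of one class.

    PV+ cells default to broader direction and frequency tuning than
    pyramidal cells.
    """

    sigma_dir: tuple[float, float] = (10.0, 40.0)
    sigma_xy: tuple[float, float] = (0.5, 1.5)
    q: tuple[float, float] = (0.0, 0.6)
    r_max: tuple[float, float] = (0.5, 2.0)
    b: tuple[float, float] = (-0.02, 0.05)
    noise_sd: tuple[float, float] = (0.04, 0.08)

    def __post_init__(self):
        for name in ("sigma_dir", "sigma_xy", "q", "r_max", "b", "noise_sd"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"invalid {name} bounds: {lo} > {hi}")


def default_profiles() -> dict[str, ClassProfile]:
    return {
        PYR: ClassProfile(),
        PV: ClassProfile(sigma_dir=(40.0, 120.0), sigma_xy=(1.5, 3.5),
                         q=(0.2, 1.0)),
    }


@dataclass
class GroundTruthCell:
    cell_id: int
    cell_class: str  # PV or PYR
    position: np.ndarray  # (x, y, z) in um
    tuning: TuningParams
    noise_sd: float
    response_gain: float
    plane: int = 0


@dataclass
class TrialTensor:
    """dF/F indexed by (cell, stimulus, rep, frame) plus stimulus metadata."""

    f: np.ndarray  # (n_cells, n_stim, n_rep, n_frames)
    ensemble: StimulusEnsemble

    def roi(self, i: int) -> np.ndarray:
        return self.f[i]

    @property
    def n_cells(self) -> int:
        return self.f.shape[0]

    @property
    def n_rep(self) -> int:
        return self.f.shape[2]

    @property
    def moving_window(self) -> tuple[int, int]:
        return self.ensemble.moving_window


def gen_cells(
    n_pv: int,
    n_pyr: int,
    ensemble: StimulusEnsemble | None = None,
    profiles: dict[str, ClassProfile] | None = None,
    seed: int | np.random.Generator = 0,
    volume_um: tuple[float, float, float] = (400.0, 400.0, 80.0),
    n_planes: int = 8,
) -> list[GroundTruthCell]:
    """Draw ground-truth cells with class-specific tuning breadth.

    PV+ cells are sampled with broader sigma_dir / sigma_x / sigma_y ranges
    than pyramidal cells so class medians separate in expectation.
    """
    if n_pv < 0 or n_pyr < 0:
        raise ValueError("cell counts must be >= 0")
    ensemble = ensemble or default_ensemble()
    profiles = profiles or default_profiles()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    sf_oct = ensemble.sf_octaves
    tf_oct = ensemble.tf_octaves
    cells = []
    classes = [PV] * n_pv + [PYR] * n_pyr
    for cid, cls in enumerate(classes):
        pr = profiles[cls]
        params = TuningParams(
            b=rng.uniform(*pr.b),
            r_max=rng.uniform(*pr.r_max),
            sf_pref=rng.uniform(sf_oct.min(), sf_oct.max()),
            tf_pref=rng.uniform(tf_oct.min(), tf_oct.max()),
            alpha=rng.uniform(0, 90),
            sigma_x=rng.uniform(*pr.sigma_xy),
            sigma_y=rng.uniform(*pr.sigma_xy),
            sigma_dir=rng.uniform(*pr.sigma_dir),
            q=rng.uniform(*pr.q),
            theta_pref=rng.uniform(0, 360),
        )
        z_plane = int(rng.integers(n_planes))
        pos = np.array([
            rng.uniform(0, volume_um[0]),
            rng.uniform(0, volume_um[1]),
            z_plane * volume_um[2] / max(n_planes - 1, 1),
        ])
        cells.append(GroundTruthCell(
            cell_id=cid, cell_class=cls, position=pos, tuning=params,
            noise_sd=rng.uniform(*pr.noise_sd),
            response_gain=params.r_max, plane=z_plane,
        ))
    return cells


def gen_trials(
    cells: list[GroundTruthCell],
    ensemble: StimulusEnsemble | None = None,
    n_rep: int = 8,
    seed: int | np.random.Generator = 0,
    calcium_tau_s: float = 0.7,
    kernel: str = "calcium",
    noise: str = "gaussian",
) -> TrialTensor:
    """Simulate trial-resolved dF/F traces from the tuning forward model.

    The stimulus-locked drive is the predicted moving-phase response above
    offset during moving frames (offset ``b`` throughout), passed through a
    causal single-exponential calcium kernel (unit DC gain) and corrupted
    with additive i.i.d. noise per frame.  ``kernel='identity'`` bypasses the
    indicator dynamics.
    """
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2")
    ensemble = ensemble or default_ensemble()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    theta, sf, tf = ensemble.grid()
    n_frames = ensemble.n_frames
    moving = ensemble.moving_mask

    if kernel == "calcium":
        lam = np.exp(-1.0 / (ensemble.volume_rate * calcium_tau_s))
    elif kernel == "identity":
        lam = 0.0
    else:
        raise ValueError(f"unknown kernel {kernel!r}")

    f = np.empty((len(cells), ensemble.n_stim, n_rep, n_frames))
    for k, cell in enumerate(cells):
        p = cell.tuning
        rhat = predict_response(p, theta, sf, tf)  # includes offset b
        drive = np.where(moving[None, :], (rhat - p.b)[:, None], 0.0)
        # causal exponential smoothing, unit DC gain
        sm = np.empty_like(drive)
        acc = np.zeros(drive.shape[0])
        for t in range(n_frames):
            acc = lam * acc + (1 - lam) * drive[:, t]
            sm[:, t] = acc
        mean_trace = p.b + sm  # (n_stim, n_frames)
        fk = np.repeat(mean_trace[:, None, :], n_rep, axis=1)
        if cell.noise_sd > 0:
            if noise == "gaussian":
                fk = fk + rng.normal(0, cell.noise_sd, fk.shape)
            elif noise == "laplace":
                fk = fk + rng.laplace(0, cell.noise_sd / np.sqrt(2), fk.shape)
            else:
                raise ValueError(f"unknown noise model {noise!r}")
        f[k] = fk
    return TrialTensor(f=f, ensemble=ensemble)


@dataclass
class ConnectivityParams:
    """Generator parameters for directed PV/pyramidal synaptic measurements.

    ``category_rates`` orders as (bidirectional, inhibitory-only,
    excitatory-only, unconnected).  ``rho_target`` is the target Pearson
    correlation between response similarity and log10 amplitude; the residual
    variance is split between a per-PV-cell "slice quality" offset, a latent
    strength shared by the two directions of a reciprocal pair, and i.i.d.
    noise according to ``residual_weights``.
    """

    category_rates: tuple[float, float, float, float] = (0.64, 0.15, 0.09, 0.12)
    log_amp_mean: float = -0.3   # log10 mV
    log_amp_sd: float = 0.45
    rho_target: float = 0.43
    residual_weights: tuple[float, float, float] = (0.25, 0.45, 0.30)
    n_pairs: int | None = None
    pyr_per_pv: int = 4

    def __post_init__(self):
        if not -1.0 < self.rho_target < 1.0:
            raise ValueError("rho_target must lie in (-1, 1)")
        if abs(sum(self.category_rates) - 1.0) > 1e-6:
            raise ValueError("category_rates must sum to 1")


@dataclass
class SynthConnection:
    """One directed synaptic measurement produced by the generator."""

    pre_id: int
    post_id: int
    direction: str  # 'PV->Pyr' or 'Pyr->PV'
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


def gen_connections(
    cells: list[GroundTruthCell],
    trials: TrialTensor,
    params: ConnectivityParams | None = None,
    seed: int | np.random.Generator = 0,
) -> list[SynthConnection]:
    """Draw directed connections whose log strength tracks response similarity.

    Pairs are formed between each PV+ cell and ``pyr_per_pv`` sampled
    pyramidal cells (or until ``n_pairs`` is reached).  Connection category
    is multinomial with the configured rates.  For connected directions,

        log10 amp = mean + sd * (rho * z_sim + sqrt(1-rho^2) * eps)

    with z_sim the standardized response similarity of the pair and eps a
    unit-variance mix of the per-PV offset, the within-pair latent, and
    i.i.d. noise.
    """
    params = params or ConnectivityParams()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    pv_ids = [c.cell_id for c in cells if c.cell_class == PV]
    pyr_ids = [c.cell_id for c in cells if c.cell_class == PYR]
    if not pv_ids or not pyr_ids:
        return []
    pos = {c.cell_id: c.position for c in cells}

    # candidate pairs: each PV with sampled distinct pyramids
    pairs = []
    for pv in pv_ids:
        k = min(params.pyr_per_pv, len(pyr_ids))
        chosen = rng.choice(pyr_ids, size=k, replace=False)
        pairs.extend((pv, int(py)) for py in chosen)
        if params.n_pairs is not None and len(pairs) >= params.n_pairs:
            pairs = pairs[: params.n_pairs]
            break

    # response similarity per pair from the generated trials
    r_all = {}
    for c in cells:
        r_it, _ = stimulus_means(trials.roi(c.cell_id), trials.moving_window)
        r_all[c.cell_id] = r_it
    sims = np.array([response_similarity(r_all[a], r_all[b]) for a, b in pairs])
    s_sd = sims.std()
    z_sim = (sims - sims.mean()) / s_sd if s_sd > 0 else np.zeros_like(sims)

    w_cell, w_pair, w_noise = params.residual_weights
    w_tot = w_cell + w_pair + w_noise
    w_cell, w_pair, w_noise = w_cell / w_tot, w_pair / w_tot, w_noise / w_tot
    rho = params.rho_target
    resid_scale = np.sqrt(1 - rho ** 2)
    cell_offsets = {pv: rng.normal() for pv in pv_ids}

    cats = rng.choice(4, size=len(pairs), p=params.category_rates)
    conns: list[SynthConnection] = []
    for (pv, py), cat, z in zip(pairs, cats, z_sim):
        has_i = cat in (0, 1)   # PV->Pyr present
        has_e = cat in (0, 2)   # Pyr->PV present
        latent = rng.normal()
        dist = float(np.linalg.norm(pos[pv] - pos[py]))
        for direction, present in (("PV->Pyr", has_i), ("Pyr->PV", has_e)):
            pre, post = (pv, py) if direction == "PV->Pyr" else (py, pv)
            if not present:
                conns.append(SynthConnection(pre, post, direction, False, None,
                                             distance_um=dist))
                continue
            eps = (np.sqrt(w_cell) * cell_offsets[pv]
                   + np.sqrt(w_pair) * latent
                   + np.sqrt(w_noise) * rng.normal())
            log_amp = (params.log_amp_mean
                       + params.log_amp_sd * (rho * z + resid_scale * eps))
            conns.append(SynthConnection(
                pre, post, direction, True, float(10.0 ** log_amp),
                tau_r_ms=float(rng.uniform(0.5, 3.0)),
                tau_d_ms=float(np.exp(rng.normal(np.log(12.0), 0.45))),
                p_shape=float(rng.uniform(1.0, 3.0)),
                ppr=float(np.exp(rng.normal(np.log(0.8), 0.25))),
                distance_um=dist,
            ))
    return conns


def psp_shape(t_ms: np.ndarray, tau_r: float, tau_d: float, p: float) -> np.ndarray:
    """Unit-free multiexponential PSP shape (1-exp(-t/tau_r))^p * exp(-t/tau_d)."""
    t = np.asarray(t_ms, float)
    out = np.zeros_like(t)
    m = t > 0
    out[m] = (1 - np.exp(-t[m] / tau_r)) ** p * np.exp(-t[m] / tau_d)
    return out


def psp_peak_time(tau_r: float, tau_d: float, p: float) -> float:
    """Analytic argmax of the PSP shape: t* = -tau_r * ln(tau_r/(tau_r + p tau_d))."""
    x = tau_r / (tau_r + p * tau_d)
    return float(-tau_r * np.log(x))


@dataclass
class PSPTrace:
    time_ms: np.ndarray
    voltage_mv: np.ndarray
    presyn_spike_times_ms: np.ndarray
    polarity: str  # 'EPSP' | 'IPSP'
    baseline_window_ms: float = 5.0
    multi_spike_first_pulse: bool = False


def gen_psp_trace(
    amplitude_mv: float,
    tau_r: float,
    tau_d: float,
    p: float = 2.0,
    polarity: str = "EPSP",
    noise_sd: float = 0.0,
    dt_ms: float = 0.1,
    duration_ms: float = 120.0,
    onset_ms: float = 10.0,
    baseline_mv: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> PSPTrace:
    """Synthesize a single PSP with exact extremum magnitude ``amplitude_mv``."""
    if amplitude_mv <= 0 or tau_r <= 0 or tau_d <= 0:
        raise ValueError("amplitude and time constants must be positive")
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t = np.arange(0.0, duration_ms, dt_ms)
    shape = psp_shape(t - onset_ms, tau_r, tau_d, p)
    # scale against the sampled maximum so the trace extremum is exact
    peak = shape.max()
    if peak <= 0:
        raise ValueError("PSP peak falls outside the trace duration")
    sign = -1.0 if polarity == "IPSP" else 1.0
    v = baseline_mv + sign * amplitude_mv * shape / peak
    if noise_sd > 0:
        v = v + rng.normal(0, noise_sd, v.shape)
    return PSPTrace(t, v, np.array([onset_ms]), polarity)


def gen_paired_pulse_trace(
    amplitude_mv: float,
    ppr: float,
    tau_r: float,
    tau_d: float,
    p: float = 2.0,
    polarity: str = "EPSP",
    isi_ms: float = 1000.0 / 30.0,
    noise_sd: float = 0.0,
    dt_ms: float = 0.1,
    duration_ms: float = 200.0,
    onset_ms: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> PSPTrace:
    """Two superposed PSPs at 30 Hz with second/first amplitude ratio ``ppr``."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t = np.arange(0.0, duration_ms, dt_ms)
    peak = psp_shape(np.array([psp_peak_time(tau_r, tau_d, p)]), tau_r, tau_d, p)[0]
    sign = -1.0 if polarity == "IPSP" else 1.0
    unit = sign * amplitude_mv / peak
    v = unit * psp_shape(t - onset_ms, tau_r, tau_d, p)
    v = v + ppr * unit * psp_shape(t - onset_ms - isi_ms, tau_r, tau_d, p)
    if noise_sd > 0:
        v = v + rng.normal(0, noise_sd, v.shape)
    return PSPTrace(t, v, np.array([onset_ms, onset_ms + isi_ms]), polarity)


@dataclass
class SyntheticPairedDataset:
    cells: list[GroundTruthCell]
    trials: TrialTensor
    connections: list[SynthConnection]
    connectivity_params: ConnectivityParams
    seed: int


def gen_dataset(
    n_pv: int = 10,
    n_pyr: int = 60,
    n_rep: int = 8,
    ensemble: StimulusEnsemble | None = None,
    connectivity: ConnectivityParams | None = None,
    profiles: dict[str, ClassProfile] | None = None,
    seed: int = 0,
) -> SyntheticPairedDataset:
    """One-call generation of a full synthetic paired dataset.

    A single seed fans out deterministically to the cell, trial, and
    connection generators.
    """
    ss = np.random.SeedSequence(seed)
    r_cells, r_trials, r_conn = (np.random.default_rng(s) for s in ss.spawn(3))
    ensemble = ensemble or default_ensemble()
    cells = gen_cells(n_pv, n_pyr, ensemble, profiles, seed=r_cells)
    trials = gen_trials(cells, ensemble, n_rep=n_rep, seed=r_trials)
    conns = gen_connections(cells, trials, connectivity, seed=r_conn)
    return SyntheticPairedDataset(cells, trials, conns,
                                  connectivity or ConnectivityParams(), seed)
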
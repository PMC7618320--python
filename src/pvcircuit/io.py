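"""Dataset directory read/write.

A dataset directory contains ``trials.h5`` (dF/F tensor + stimulus table),
``cells.csv``, ``connections.csv``, and ``meta.yaml``.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .ensemble import StimulusEnsemble
from .synthgen import (GroundTruthCell, SynthConnection, SyntheticPairedDataset,
                       TrialTensor, ConnectivityParams)
from .tuning import TuningParams

__all__ = ["save_dataset", "load_dataset"]

_CELL_COLS = ["cell_id", "cell_class", "x", "y", "z", "plane", "noise_sd",
              "response_gain"]
_PARAM_COLS = ["b", "r_max", "sf_pref", "tf_pref", "alpha", "sigma_x",
               "sigma_y", "sigma_dir", "q", "theta_pref"]


def save_dataset(ds: SyntheticPairedDataset, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ens = ds.trials.ensemble

    with h5py.File(out / "trials.h5", "w") as h5:
        h5.create_dataset("dff", data=ds.trials.f, compression="gzip")
        g = h5.create_group("ensemble")
        g.create_dataset("directions", data=ens.directions)
        g.create_dataset("spatial_freqs", data=ens.spatial_freqs)
        g.create_dataset("temporal_freqs", data=ens.temporal_freqs)
        g.attrs["n_stationary_frames"] = ens.n_stationary_frames
        g.attrs["n_moving_frames"] = ens.n_moving_frames
        g.attrs["moving_window"] = ens.moving_window
        g.attrs["volume_rate"] = ens.volume_rate

    rows = []
    for c in ds.cells:
        row = {"cell_id": c.cell_id, "cell_class": c.cell_class,
               "x": c.position[0], "y": c.position[1], "z": c.position[2],
               "plane": c.plane, "noise_sd": c.noise_sd,
               "response_gain": c.response_gain}
        row.update({f"gt_{k}": v for k, v in asdict(c.tuning).items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "cells.csv", index=False)

    pd.DataFrame([asdict(c) for c in ds.connections]).to_csv(
        out / "connections.csv", index=False)

    meta = {"seed": ds.seed,
            "connectivity_params": asdict(ds.connectivity_params)}
    meta["connectivity_params"]["category_rates"] = list(
        ds.connectivity_params.category_rates)
    meta["connectivity_params"]["residual_weights"] = list(
        ds.connectivity_params.residual_weights)
    (out / "meta.yaml").write_text(yaml.safe_dump(meta))
    return out


def load_dataset(in_dir: str | Path) -> SyntheticPairedDataset:
    src = Path(in_dir)
    if not src.is_dir():
        raise FileNotFoundError(f"dataset directory not found: {src}")
    with h5py.File(src / "trials.h5", "r") as h5:
        f = h5["dff"][...]
        g = h5["ensemble"]
        ens = StimulusEnsemble(
            directions=g["directions"][...],
            spatial_freqs=g["spatial_freqs"][...],
            temporal_freqs=g["temporal_freqs"][...],
            n_stationary_frames=int(g.attrs["n_stationary_frames"]),
            n_moving_frames=int(g.attrs["n_moving_frames"]),
            moving_window=tuple(int(v) for v in g.attrs["moving_window"]),
            volume_rate=float(g.attrs["volume_rate"]),
        )
    trials = TrialTensor(f=f, ensemble=ens)

    cells_df = pd.read_csv(src / "cells.csv")
    cells = []
    for _, r in cells_df.iterrows():
        params = TuningParams(**{k: float(r[f"gt_{k}"]) for k in _PARAM_COLS})
        cells.append(GroundTruthCell(
            cell_id=int(r.cell_id), cell_class=str(r.cell_class),
            position=np.array([r.x, r.y, r.z]), tuning=params,
            noise_sd=float(r.noise_sd), response_gain=float(r.response_gain),
            plane=int(r.plane)))

    conn_df = pd.read_csv(src / "connections.csv")
    conns = []
    for _, r in conn_df.iterrows():
        amp = None if pd.isna(r.amplitude_mv) else float(r.amplitude_mv)
        conns.append(SynthConnection(
            pre_id=int(r.pre_id), post_id=int(r.post_id),
            direction=str(r.direction), connected=bool(r.connected),
            amplitude_mv=amp,
            tau_r_ms=None if pd.isna(r.tau_r_ms) else float(r.tau_r_ms),
            tau_d_ms=None if pd.isna(r.tau_d_ms) else float(r.tau_d_ms),
            p_shape=None if pd.isna(r.p_shape) else float(r.p_shape),
            ppr=None if pd.isna(r.ppr) else float(r.ppr),
            distance_um=float(r.distance_um), n_trials=int(r.n_trials)))

    meta = yaml.safe_load((src / "meta.yaml").read_text())
    cp = meta["connectivity_params"]
    cp["category_rates"] = tuple(cp["category_rates"])
    cp["residual_weights"] = tuple(cp["residual_weights"])
    params = ConnectivityParams(**cp)
    return SyntheticPairedDataset(cells, trials, conns, params,
                                  seed=int(meta["seed"]))
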
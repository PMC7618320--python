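"""Pipeline orchestration: synth -> preprocess -> tuning -> similarity ->
synaptic stats -> report, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dsio
from .ensemble import default_ensemble
from .synthgen import (ConnectivityParams, gen_dataset, PV, PYR)
from . import tuning as tn
from . import similarity as sm
from . import synaptic as sy

logger = logging.getLogger(__name__)

__all__ = ["default_config", "run_pipeline", "report",
            "tuning_table", "pairs_table", "connectivity_stats"]

STAGES = ("synth", "preprocess", "tuning", "similarity", "synaptic")


def default_config() -> dict:
    return {
        "n_pv": 10,
        "n_pyr": 60,
        "n_rep": 8,
        "seed": 0,
        "connectivity": {},
        "tuning": {"n_restarts": 20},
        "n_shuffles": 2000,
    }


def _stage_seeds(seed: int) -> dict[str, int]:
    """Fan a global seed out to fixed per-stage seeds."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES))
    return {name: int(c.generate_state(1)[0]) for name, c in zip(STAGES, children)}


def tuning_table(ds, n_restarts: int = 20, seed: int = 0) -> pd.DataFrame:
    """Per-ROI responsiveness, selectivity, tuning fit, and FWHM features."""
    rows = []
    ens = ds.trials.ensemble
    for c in ds.cells:
        f = ds.trials.roi(c.cell_id)
        r2 = tn.variance_explained(f)
        _, rbar = tn.stimulus_means(f, ens.moving_window)
        try:
            skew = tn.selectivity_skewness(rbar)
        except ValueError:
            skew = np.nan
        row = {"cell_id": c.cell_id, "cell_class": c.cell_class,
               "r2": r2, "responsive": r2 > tn.RESPONSIVE_THRESHOLD,
               "selectivity": skew}
        if row["responsive"]:
            fit = tn.fit_tuning(f, ens, n_restarts=n_restarts,
                                seed=seed + c.cell_id)
            row.update({k: v for k, v in fit.params.as_dict().items()})
            row.update({"sse": fit.sse, "fwhm_dir": fit.fwhm_dir,
                        "fwhm_sf": fit.fwhm_sf, "fwhm_tf": fit.fwhm_tf,
                        "tuned_dir": fit.tuned_dir, "tuned_sf": fit.tuned_sf,
                        "tuned_tf": fit.tuned_tf})
        rows.append(row)
    return pd.DataFrame(rows)


def pairs_table(ds) -> pd.DataFrame:
    """Similarity metrics for every generated PV/pyramidal pair."""
    ens = ds.trials.ensemble
    cells = {c.cell_id: c for c in ds.cells}
    r_by_cell = {}
    rbar_by_cell = {}
    for c in ds.cells:
        r_it, rbar = tn.stimulus_means(ds.trials.roi(c.cell_id), ens.moving_window)
        r_by_cell[c.cell_id] = r_it
        rbar_by_cell[c.cell_id] = rbar

    seen = set()
    rows = []
    for conn in ds.connections:
        pv, py = ((conn.pre_id, conn.post_id) if conn.direction == "PV->Pyr"
                  else (conn.post_id, conn.pre_id))
        if (pv, py) in seen:
            continue
        seen.add((pv, py))
        a, b = cells[pv], cells[py]
        keep = sm.exclude_close_pairs(a.position[None], b.position[None],
                                      np.array([a.plane]), np.array([b.plane]))[0]
        rows.append({
            "pv_id": pv, "pyr_id": py,
            "response_similarity": sm.response_similarity(
                r_by_cell[pv], r_by_cell[py]),
            "total_similarity": sm.total_similarity(
                ds.trials.roi(pv), ds.trials.roi(py)),
            "signal_similarity_time_avg": sm.signal_similarity_time_avg(
                rbar_by_cell[pv], rbar_by_cell[py]),
            "total_correlation": sm.total_correlation(
                ds.trials.roi(pv), ds.trials.roi(py)),
            "signal_correlation": sm.signal_correlation(
                r_by_cell[pv], r_by_cell[py]),
            "distance_um": float(np.linalg.norm(a.position - b.position)),
            "keep": bool(keep),
        })
    return pd.DataFrame(rows)


def connectivity_stats(ds, pairs: pd.DataFrame, n_shuffles: int = 2000,
                       seed: int = 0,
                       responsive_pyr: set[int] | None = None) -> dict:
    """Headline connectivity statistics of one dataset.

    Strength analyses are restricted to pairs surviving the exclusion rules
    (close-pair filter from the similarity stage, slow-decay cutoff, and the
    pyramidal responsiveness gate when ``responsive_pyr`` is given).
    """
    pair_keep = {(r.pv_id, r.pyr_id): bool(r.keep) for r in pairs.itertuples()}
    exclusions = sy.exclusion_table(ds.connections, pair_keep, responsive_pyr)
    kept = {(r.pv_id, r.pyr_id, r.direction): r.kept
            for r in exclusions.itertuples()}
    sim_by_pair = {(r.pv_id, r.pyr_id): r.response_similarity
                   for r in pairs.itertuples() if r.keep}
    stats: dict = {}

    # category contingency over pairs probed in both directions
    by_pair: dict[tuple, dict] = {}
    for c in ds.connections:
        pv, py = ((c.pre_id, c.post_id) if c.direction == "PV->Pyr"
                  else (c.post_id, c.pre_id))
        d = by_pair.setdefault((pv, py), {})
        d["i" if c.direction == "PV->Pyr" else "e"] = c.connected
    counts = {"bidirectional": 0, "inhibitory_only": 0,
              "excitatory_only": 0, "unconnected": 0}
    for d in by_pair.values():
        if len(d) < 2:
            continue
        key = {(True, True): "bidirectional", (True, False): "inhibitory_only",
               (False, True): "excitatory_only",
               (False, False): "unconnected"}[(d["i"], d["e"])]
        counts[key] += 1
    stats["categories"] = sy.category_percentages(counts)
    stats["category_counts"] = counts

    # similarity vs log amplitude, per direction
    for direction, name in (("PV->Pyr", "ipsp"), ("Pyr->PV", "epsp")):
        xs, ys, dist = [], [], []
        for c in ds.connections:
            if c.direction != direction or not c.connected:
                continue
            pv, py = ((c.pre_id, c.post_id) if direction == "PV->Pyr"
                      else (c.post_id, c.pre_id))
            if not kept.get((pv, py, direction), True):
                continue
            s = sim_by_pair.get((pv, py))
            if s is None or not np.isfinite(s):
                continue
            xs.append(s)
            ys.append(c.log10_amplitude)
            dist.append(c.distance_um)
        if len(xs) >= 4:
            from scipy.stats import pearsonr
            r, p = pearsonr(xs, ys)
            stats[f"similarity_log_{name}"] = {
                "r": float(r), "p": float(p), "n": len(xs),
                "pct_variance": sy.percent_variance_from_correlation(r)}
            try:
                rp, pp = sy.partial_correlation(xs, ys, dist)
                stats[f"similarity_log_{name}_partial_distance"] = {
                    "r": rp, "p": pp}
            except ValueError:
                pass

    # reciprocal correlation, normalization, permutation test
    try:
        r, p, n = sy.reciprocal_correlation(ds.connections)
        stats["reciprocal"] = {"r": r, "p": p, "n": n}
    except ValueError:
        stats["reciprocal"] = None
    norm = sy.normalize_within_presyn(ds.connections)
    if len(norm):
        try:
            r_ei, p_perm = sy.permutation_test(norm, n_shuffles=n_shuffles,
                                               seed=seed)
            stats["normalized_permutation"] = {
                "r": r_ei, "p": p_perm, "n": int(len(norm))}
        except ValueError:
            stats["normalized_permutation"] = None

    # connection probability vs similarity (PV->Pyr)
    xs, flags = [], []
    for c in ds.connections:
        if c.direction != "PV->Pyr":
            continue
        s = sim_by_pair.get((c.pre_id, c.post_id))
        if s is None:
            continue
        xs.append(s)
        flags.append(c.connected)
    if len(set(flags)) == 2:
        fit = sy.connection_probability_model(np.array(xs), np.array(flags))
        stats["connection_probability"] = {
            "slope": fit.slope, "p": fit.p_value, "separated": fit.separated,
            "n": len(xs)}
    return stats


def run_pipeline(config: dict | None = None, out_dir: str | Path = "runs/latest",
                 resume: bool = True) -> dict:
    """Run the full analysis pipeline; returns the manifest.

    Stages execute in order, each seeded from a fixed fan-out of the global
    seed; completed stage outputs are reused on rerun when ``resume``.
    """
    cfg = default_config()
    cfg.update(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg["seed"])
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
    manifest = {"config": cfg, "config_hash": cfg_hash, "seeds": seeds,
                "stages": {}, "out_dir": str(out)}

    def stage(name):
        def deco(fn):
            t0 = time.monotonic()
            try:
                fn()
            except Exception as e:
                raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e
            dt = time.monotonic() - t0
            manifest["stages"][name] = {"seed": seeds[name],
                                        "elapsed_s": round(dt, 3)}
            logger.info("stage %s done in %.2fs", name, dt)
        return deco

    data_dir = out / "dataset"

    @stage("synth")
    def _synth():
        if resume and (data_dir / "meta.yaml").exists():
            return
        ds = gen_dataset(n_pv=cfg["n_pv"], n_pyr=cfg["n_pyr"],
                         n_rep=cfg["n_rep"],
                         connectivity=ConnectivityParams(**cfg["connectivity"]),
                         seed=seeds["synth"])
        dsio.save_dataset(ds, data_dir)

    ds = dsio.load_dataset(data_dir)

    @stage("preprocess")
    def _pre():
        # synthetic traces are generated as dF/F; this stage validates them
        if not np.all(np.isfinite(ds.trials.f)):
            raise ValueError("non-finite dF/F values")

    @stage("tuning")
    def _tuning():
        path = out / "tuning.csv"
        if resume and path.exists():
            return
        tuning_table(ds, seed=seeds["tuning"],
                     **cfg.get("tuning", {})).to_csv(path, index=False)

    @stage("similarity")
    def _similarity():
        path = out / "pairs.csv"
        if resume and path.exists():
            return
        pairs_table(ds).to_csv(path, index=False)

    @stage("synaptic")
    def _synaptic():
        path = out / "stats.json"
        if resume and path.exists():
            return
        pairs = pd.read_csv(out / "pairs.csv")
        tuning_df = pd.read_csv(out / "tuning.csv")
        responsive = set(tuning_df.loc[
            tuning_df.responsive & (tuning_df.cell_class == PYR),
            "cell_id"].astype(int))
        pair_keep = {(r.pv_id, r.pyr_id): bool(r.keep)
                     for r in pairs.itertuples()}
        sy.exclusion_table(ds.connections, pair_keep, responsive).to_csv(
            out / "filtered_pairs.csv", index=False)
        stats = connectivity_stats(ds, pairs, n_shuffles=cfg["n_shuffles"],
                                   seed=seeds["synaptic"],
                                   responsive_pyr=responsive)
        path.write_text(json.dumps(stats, indent=2, default=float))

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return "undefined"
    if isinstance(v, float):
        return f"{v:.3g}"
    return str(v)


def report(stats: dict, sim_summaries: dict | None = None) -> str:
    """Human-readable summary of the headline numbers."""
    lines = ["connectivity summary", "===================="]
    cats = stats.get("categories")
    if cats is None or cats.get("n", 0) == 0:
        lines.append("no pairs probed in both directions")
    else:
        n = cats["n"]
        lines.append(f"pairs probed in both directions: {n}")
        for k in ("bidirectional", "inhibitory_only", "excitatory_only",
                  "unconnected"):
            lines.append(f"  {k}: {_fmt(cats[k])}%")
    for key, label in (("similarity_log_ipsp", "similarity vs log IPSP"),
                       ("similarity_log_epsp", "similarity vs log EPSP")):
        if key in stats:
            s = stats[key]
            lines.append(f"{label}: R={_fmt(s['r'])} p={_fmt(s['p'])} "
                         f"(n={s['n']}, {_fmt(s['pct_variance'])}% variance)")
    if stats.get("reciprocal"):
        s = stats["reciprocal"]
        lines.append(f"reciprocal log EPSP vs log IPSP: R={_fmt(s['r'])} "
                     f"p={_fmt(s['p'])} (n={s['n']})")
    if stats.get("normalized_permutation"):
        s = stats["normalized_permutation"]
        lines.append(f"normalized E/I correlation: R={_fmt(s['r'])} "
                     f"permutation p={_fmt(s['p'])} (n={s['n']})")
    if stats.get("connection_probability"):
        s = stats["connection_probability"]
        lines.append(f"connection probability slope={_fmt(s['slope'])} "
                     f"p={_fmt(s['p'])} (n={s['n']})")
    for name, summ in (sim_summaries or {}).items():
        lines.append(f"simulation [{name}]: " + ", ".join(
            f"{k}={_fmt(v)}" for k, v in summ.items()))
    return "\n".join(lines)
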
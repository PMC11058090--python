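"""End-to-end orchestration: simulate -> preprocess -> events -> extract ->
classify -> metrics -> stats.

Each stage is a function over files in an output directory, so stages can be
run individually (the CLI maps onto them one-to-one) or chained with
:func:`run_pipeline`. Every run records the resolved configuration and its
hash; reruns with an identical configuration produce byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .classification import classify_synergies
from .emg import normalize_amplitude, preprocess_emg, segment_cycles
from .events import coefficient_of_variation, detect_events, temporal_parameters
from .extraction import average_repetitions, select_rank
from .metrics import similarity_series
from .stats import perturbation_contrasts
from .synthetic import SynergySpec, synthesize_raw_signals

__all__ = ["default_config", "load_config", "config_hash", "run_pipeline",
           "stage_simulate", "stage_preprocess", "stage_events",
           "stage_extract", "stage_classify", "stage_metrics", "stage_stats"]

log = logging.getLogger("syngait")


def default_config() -> dict:
    """Documented configuration keys with their defaults."""
    return {
        "seed": 0,
        "outdir": "syngait_out",
        "simulation": {
            "n_cycles": 12,
            "perturbed_cycle_index": 3,
            "noise_sd": 0.05,
            "coa_shift": -0.3,
            "widen_factor": 1.5,
            "stance_s": 0.7,
            "swing_s": 0.4,
            "fs_emg": 2000.0,
            "fs_accel": 143.0,
        },
        "emg": {"hp_cutoff": 50.0, "lp_cutoff": 20.0},
        "events": {"min_cycle_s": 0.6, "liftoff_correction_s": 0.003},
        "nmf": {"rank": 4, "n_repetitions": 20, "max_rank": 10, "flat_mse": 1e-4},
        "classification": {"max_k": 13, "similarity_floor": 0.75},
        "direction": "mediolateral",
        "predictability": "unpredictable",
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if k not in base:
            raise KeyError(f"unknown configuration key: {k!r}")
        if isinstance(v, dict) and isinstance(base[k], dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, **overrides) -> dict:
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    return _merge(cfg, overrides)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _outdir(cfg: dict) -> Path:
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    return out


def stage_simulate(cfg: dict) -> Path:
    out = _outdir(cfg)
    sim = cfg["simulation"]
    spec = SynergySpec(
        n_cycles=sim["n_cycles"],
        perturbed_cycle_index=sim["perturbed_cycle_index"],
        noise_sd=sim["noise_sd"],
        coa_shift=sim["coa_shift"],
        widen_factor=sim["widen_factor"],
        stance_s=sim["stance_s"],
        swing_s=sim["swing_s"],
        seed=cfg["seed"],
    )
    trial, trace, events, gt = synthesize_raw_signals(
        spec, fs_emg=sim["fs_emg"], fs_accel=sim["fs_accel"]
    )
    sio.write_emg_trial(out / "emg_raw.csv", trial)
    sio.write_accel_trace(out / "accel.csv", trace)
    sio.write_events(out / "events_true.csv", events)
    sidecar = {
        "seed": cfg["seed"],
        "prototypes": [
            {"label": p.label, "phase_center": p.phase_center,
             "concentration": p.concentration,
             "dominant_muscles": list(p.dominant_muscles)}
            for p in spec.prototypes
        ],
        "coa_shift": spec.coa_shift,
        "widen_factor": spec.widen_factor,
        "perturbed_cycle_index": spec.perturbed_cycle_index,
    }
    (out / "ground_truth.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=True))
    log.info("simulated trial: %d cycles, %d muscles", sim["n_cycles"], 13)
    return out


def stage_preprocess(cfg: dict) -> Path:
    out = _outdir(cfg)
    trial = sio.read_emg_trial(out / "emg_raw.csv",
                               direction=cfg["direction"],
                               predictability=cfg["predictability"])
    env = preprocess_emg(trial, hp_cutoff=cfg["emg"]["hp_cutoff"],
                         lp_cutoff=cfg["emg"]["lp_cutoff"])
    sio.write_emg_trial(out / "emg_envelopes.csv", env)
    return out


def stage_events(cfg: dict) -> Path:
    out = _outdir(cfg)
    trace = sio.read_accel_trace(out / "accel.csv")
    events = detect_events(trace, min_cycle_s=cfg["events"]["min_cycle_s"])
    sio.write_events(out / "events.csv", events)
    temporal = temporal_parameters(events)
    sio.write_table(out / "temporal.csv", temporal)
    cv = pd.DataFrame(
        {
            "parameter": ["t_st", "t_sw", "cadence", "duty_factor"],
            "cv": [coefficient_of_variation(temporal[c]) for c in
                   ("t_st", "t_sw", "cadence", "duty_factor")],
        }
    )
    sio.write_table(out / "cv_summary.csv", cv)
    log.info("detected %d cycles", events.n_cycles)
    return out


def stage_extract(cfg: dict) -> Path:
    out = _outdir(cfg)
    env = sio.read_emg_trial(out / "emg_envelopes.csv")
    events = sio.read_events(out / "events.csv")
    normalized = normalize_amplitude(env.samples, env.muscle_labels)
    cycles = segment_cycles(normalized, env.fs, events.touchdowns, events.liftoffs)

    long_rows = []
    for cyc in cycles:
        df = pd.DataFrame(cyc.V.T, columns=list(cyc.muscle_labels))
        df.insert(0, "point", np.arange(cyc.n_points))
        df.insert(0, "cycle", cyc.cycle_index)
        long_rows.append(df)
    sio.write_table(out / "cycles.csv", pd.concat(long_rows, ignore_index=True))

    nmf = cfg["nmf"]
    rank = nmf["rank"]
    if rank in (None, "auto"):
        rank, curve = select_rank(
            cycles[0], max_rank=nmf["max_rank"], seed=cfg["seed"],
            flat_mse=nmf["flat_mse"],
        )
        log.info("selected rank %d (R^2 curve: %s)", rank, np.round(curve, 4))
    sets = [
        average_repetitions(cyc, rank, n_rep=nmf["n_repetitions"],
                            seed=cfg["seed"] + cyc.cycle_index)
        for cyc in cycles
    ]
    sio.write_synergy_sets(out / "synergies.txt", sets)
    return out


def stage_classify(cfg: dict) -> Path:
    out = _outdir(cfg)
    sets = sio.read_synergy_sets(out / "synergies.txt")
    labels, result = classify_synergies(
        sets, seed=cfg["seed"],
        max_k=cfg["classification"]["max_k"],
        similarity_floor=cfg["classification"]["similarity_floor"],
    )
    rows = []
    i = 0
    for s, labs in zip(sets, labels):
        for j, lab in enumerate(labs):
            rows.append(dict(cycle=s.cycle_index, synergy=j, label=lab,
                             centroid_similarity=result.centroid_similarity[i]))
            i += 1
    sio.write_table(out / "labels.csv", pd.DataFrame(rows))
    log.info("classified %d synergies, %.1f%% non-classifiable",
             len(result.labels), 100 * result.fraction_non_classifiable)
    return out


def stage_metrics(cfg: dict) -> Path:
    out = _outdir(cfg)
    sets = sio.read_synergy_sets(out / "synergies.txt")
    lab_df = pd.read_csv(out / "labels.csv")
    labels = [
        list(lab_df[lab_df["cycle"] == s.cycle_index].sort_values("synergy")["label"])
        for s in sets
    ]
    series = similarity_series(sets, reference_index=0, labels=labels)
    series.insert(0, "predictability", cfg["predictability"])
    series.insert(0, "direction", cfg["direction"])
    sio.write_table(out / "metrics.csv", series)
    return out


def stage_stats(cfg: dict) -> Path:
    out = _outdir(cfg)
    metrics = pd.read_csv(out / "metrics.csv")
    contrasts = perturbation_contrasts(
        metrics,
        perturbed_cycle=cfg["simulation"]["perturbed_cycle_index"],
    )
    sio.write_table(out / "stats.csv", contrasts)
    return out


_STAGES = (
    stage_simulate,
    stage_preprocess,
    stage_events,
    stage_extract,
    stage_classify,
    stage_metrics,
    stage_stats,
)


def run_pipeline(config_path=None, cfg: dict | None = None, **overrides) -> Path:
    """Run all stages in order and return the output directory.

    Either pass a YAML ``config_path`` plus keyword overrides, or a fully
    resolved ``cfg`` dict.
    """
    if cfg is None:
        cfg = load_config(config_path, **overrides)
    out = _outdir(cfg)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        (out / "config_resolved.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
        (out / "config_hash.txt").write_text(config_hash(cfg) + "\n")
        log.info("config hash %s", config_hash(cfg))
        for stage in _STAGES:
            log.info("running %s", stage.__name__)
            stage(cfg)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
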
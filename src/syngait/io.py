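"""Delimited-text readers and writers for every pipeline artifact.

All formats are plain text. EMG trials are CSV with a ``time`` column (s)
followed by one column per muscle code (ME, MA, FL, RF, VM, VL, ST, BF, TA,
PL, GM, GL, SO, in that order); accelerometer traces are CSV with columns
time, vertical, anteroposterior, mediolateral; events, temporal parameters,
labels and metrics are tidy CSV tables. Synergy sets use a small structured
text format (header lines, then the M and P blocks) that round-trips
exactly at full float precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .emg import EmgTrial
from .events import AccelTrace, GaitEvents
from .extraction import SynergySet
from .muscles import MUSCLE_LABELS

__all__ = [
    "write_emg_trial",
    "read_emg_trial",
    "write_accel_trace",
    "read_accel_trace",
    "write_events",
    "read_events",
    "write_synergy_sets",
    "read_synergy_sets",
    "write_table",
]

_FLOAT_FMT = "%.10g"


def write_emg_trial(path, trial: EmgTrial, t0: float = 0.0) -> None:
    t = t0 + np.arange(trial.samples.shape[1]) / trial.fs
    df = pd.DataFrame({"time": t})
    for i, lab in enumerate(trial.muscle_labels):
        df[lab] = trial.samples[i]
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_emg_trial(path, muscle_labels=MUSCLE_LABELS, **metadata) -> EmgTrial:
    df = pd.read_csv(path)
    missing = [lab for lab in muscle_labels if lab not in df.columns]
    if missing:
        raise ValueError(
            f"EMG file {path} is missing muscle column(s): {', '.join(missing)}"
        )
    t = df["time"].to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    samples = np.vstack([df[lab].to_numpy() for lab in muscle_labels])
    return EmgTrial(samples=samples, fs=float(fs), muscle_labels=tuple(muscle_labels), **metadata)


def write_accel_trace(path, trace: AccelTrace, t0: float = 0.0) -> None:
    t = t0 + np.arange(len(trace.vertical)) / trace.fs
    pd.DataFrame(
        {
            "time": t,
            "vertical": trace.vertical,
            "anteroposterior": trace.anteroposterior,
            "mediolateral": trace.mediolateral,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_accel_trace(path) -> AccelTrace:
    df = pd.read_csv(path)
    for col in ("time", "vertical", "anteroposterior", "mediolateral"):
        if col not in df.columns:
            raise ValueError(f"accelerometer file {path} is missing column {col!r}")
    fs = 1.0 / np.median(np.diff(df["time"].to_numpy()))
    return AccelTrace(
        fs=float(fs),
        vertical=df["vertical"].to_numpy(),
        anteroposterior=df["anteroposterior"].to_numpy(),
        mediolateral=df["mediolateral"].to_numpy(),
    )


def write_events(path, events: GaitEvents) -> None:
    pd.DataFrame(
        {
            "cycle": np.arange(events.n_cycles),
            "touchdown_s": events.touchdowns[:-1],
            "liftoff_s": events.liftoffs,
            "next_touchdown_s": events.touchdowns[1:],
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_events(path) -> GaitEvents:
    df = pd.read_csv(path)
    tds = np.concatenate([df["touchdown_s"].to_numpy(), df["next_touchdown_s"].to_numpy()[-1:]])
    return GaitEvents(touchdowns=tds, liftoffs=df["liftoff_s"].to_numpy())


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_synergy_sets(path, sets: list[SynergySet]) -> None:
    lines = []
    for s in sets:
        lines.append("[synergy_set]")
        lines.append(f"cycle = {s.cycle_index}")
        lines.append(f"rank = {s.rank}")
        lines.append(f"r_squared = {float(s.r_squared)!r}")
        lines.append(f"n_repetitions = {s.n_repetitions}")
        lines.append(f"seed = {s.seed}")
        lines.append("[M]")
        for row in s.M:
            lines.append(" ".join(repr(float(v)) for v in row))
        lines.append("[P]")
        for row in s.P:
            lines.append(" ".join(repr(float(v)) for v in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_synergy_sets(path) -> list[SynergySet]:
    sets: list[SynergySet] = []
    header: dict = {}
    M_rows: list[list[float]] = []
    P_rows: list[list[float]] = []
    section = None

    def flush():
        if not header:
            return
        sets.append(
            SynergySet(
                M=np.array(M_rows),
                P=np.array(P_rows),
                rank=int(header["rank"]),
                r_squared=float(header["r_squared"]),
                n_repetitions=int(header["n_repetitions"]),
                cycle_index=int(header["cycle"]),
                seed=None if header.get("seed") in (None, "None") else int(header["seed"]),
            )
        )

    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line == "[synergy_set]":
            flush()
            header, M_rows, P_rows, section = {}, [], [], "header"
        elif line == "[M]":
            section = "M"
        elif line == "[P]":
            section = "P"
        elif section == "header":
            key, _, val = line.partition("=")
            header[key.strip()] = val.strip()
        elif section == "M":
            M_rows.append([float(v) for v in line.split()])
        elif section == "P":
            P_rows.append([float(v) for v in line.split()])
    flush()
    return sets
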
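"""Surface-EMG conditioning and gait-cycle normalization.

The conditioning chain follows the standard synergy-extraction recipe:
a 4th-order Butterworth zero-phase high-pass at 50 Hz, full-wave
rectification, a 4th-order Butterworth zero-phase low-pass at 20 Hz
(the envelope), amplitude normalization per muscle to the [min, max] of
the whole trial, and time normalization of each gait cycle to a fixed
200-point grid with 100 points for stance and 100 for swing.

"Zero-phase" is realized by forward-backward application of a 4th-order
design (``scipy.signal.sosfiltfilt``), doubling the magnitude order but
cancelling the phase, so envelope peaks are not lagged relative to the
underlying bursts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .muscles import MUSCLE_LABELS

__all__ = [
    "EmgTrial",
    "NormalizedCycle",
    "preprocess_emg",
    "normalize_amplitude",
    "time_normalize_cycle",
    "segment_cycles",
]

N_POINTS = 200
STANCE_POINTS = 100
SWING_POINTS = 100


def zero_phase_filter(
    x: np.ndarray, fs: float, cutoff, btype: str, order: int = 4
) -> np.ndarray:
    """Forward-backward Butterworth filter along the last axis."""
    sos = signal.butter(order, cutoff, btype=btype, fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


@dataclass
class EmgTrial:
    """Multi-muscle surface-EMG recording of one trial.

    ``samples`` has one row per muscle label, in the order of ``muscle_labels``.
    ``direction`` and ``predictability`` carry the perturbation condition of
    the trial; they are metadata and do not affect processing.
    """

    samples: np.ndarray
    fs: float
    muscle_labels: tuple[str, ...] = MUSCLE_LABELS
    direction: str = "mediolateral"
    predictability: str = "unpredictable"
    notes: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got fs={self.fs}")
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (muscles x time) array")
        if self.samples.shape[0] != len(self.muscle_labels):
            raise ValueError(
                f"{self.samples.shape[0]} sample rows for "
                f"{len(self.muscle_labels)} muscle labels"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_muscles(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass
class NormalizedCycle:
    """One gait cycle as the m x n matrix V fed to the factorization.

    Rows are muscles (13), columns the 200 normalized time points: points
    0..99 sample the stance phase, 100..199 the swing phase. Entries are
    non-negative; after trial-wide amplitude normalization they lie in [0, 1].
    """

    V: np.ndarray
    cycle_index: int = 0
    stance_points: int = STANCE_POINTS
    swing_points: int = SWING_POINTS
    muscle_labels: tuple[str, ...] = MUSCLE_LABELS

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        n = self.stance_points + self.swing_points
        if self.V.ndim != 2 or self.V.shape[1] != n:
            raise ValueError(
                f"V must be (muscles x {n}), got shape {self.V.shape}"
            )
        if np.min(self.V) < -1e-12:
            raise ValueError("V must be non-negative")
        self.V = np.maximum(self.V, 0.0)

    @property
    def n_points(self) -> int:
        return self.V.shape[1]


def preprocess_emg(trial: EmgTrial, hp_cutoff: float = 50.0, lp_cutoff: float = 20.0) -> EmgTrial:
    """Condition raw EMG into non-negative linear envelopes.

    High-pass (zero-phase Butterworth, default 50 Hz), full-wave rectify,
    low-pass (zero-phase Butterworth, default 20 Hz). The result is clipped
    at zero: the low-pass of a rectified signal can undershoot by a small
    ripple, and every downstream stage requires non-negative input.
    """
    if trial.fs < 200.0:
        raise ValueError(
            f"fs={trial.fs} Hz is too low: the {hp_cutoff} Hz high-pass stage "
            f"requires fs >= 200 Hz (cutoff must sit well below the Nyquist "
            f"frequency fs/2={trial.fs / 2:g} Hz)"
        )
    x = zero_phase_filter(trial.samples, trial.fs, hp_cutoff, "highpass")
    x = np.abs(x)
    x = zero_phase_filter(x, trial.fs, lp_cutoff, "lowpass")
    return replace(trial, samples=np.maximum(x, 0.0))


def normalize_amplitude(envelopes: np.ndarray, muscle_labels=MUSCLE_LABELS) -> np.ndarray:
    """Normalize each muscle to [0, 1] over the whole trial.

    Per muscle, the minimum over the full trial (all consecutive cycles) is
    subtracted and the result divided by the trial-wide range. A cycle whose
    local maximum is below the trial maximum therefore keeps a peak < 1.
    """
    env = np.asarray(envelopes, dtype=float)
    lo = env.min(axis=-1, keepdims=True)
    hi = env.max(axis=-1, keepdims=True)
    span = hi - lo
    flat = np.nonzero(span[..., 0] == 0)[0]
    if flat.size:
        bad = ", ".join(muscle_labels[i] for i in flat)
        raise ValueError(
            f"constant channel(s) cannot be amplitude-normalized: {bad}"
        )
    return (env - lo) / span


def time_normalize_cycle(
    segment: np.ndarray,
    fs: float,
    touchdown: float,
    liftoff: float,
    next_touchdown: float,
    segment_start: float = 0.0,
    cycle_index: int = 0,
    muscle_labels=MUSCLE_LABELS,
) -> NormalizedCycle:
    """Resample one gait cycle onto the fixed 200-point grid.

    Stance (touchdown to lift-off) is linearly interpolated onto 100 evenly
    spaced points and swing (lift-off to next touchdown) onto another 100.
    The grid is half-open: point 0 sits exactly at touchdown, the next
    touchdown is excluded, so consecutive cycles never share a boundary
    sample. Event times are in seconds on the same clock as
    ``segment_start``.
    """
    seg = np.atleast_2d(np.asarray(segment, dtype=float))
    if not (touchdown < liftoff < next_touchdown):
        raise ValueError(
            f"events out of order: need touchdown < liftoff < next_touchdown, "
            f"got {touchdown}, {liftoff}, {next_touchdown}"
        )
    t = segment_start + np.arange(seg.shape[1]) / fs
    if t[0] > touchdown + 1e-9 or t[-1] < next_touchdown - 1.0 / fs - 1e-9:
        raise ValueError("segment does not cover the full gait cycle")
    n_stance = int(np.sum((t >= touchdown) & (t < liftoff)))
    n_swing = int(np.sum((t >= liftoff) & (t < next_touchdown)))
    if n_stance < 2 or n_swing < 2:
        raise ValueError(
            f"phase too short to resample: {n_stance} stance and {n_swing} "
            f"swing samples (need >= 2 each)"
        )
    stance_grid = touchdown + (liftoff - touchdown) * np.arange(STANCE_POINTS) / STANCE_POINTS
    swing_grid = liftoff + (next_touchdown - liftoff) * np.arange(SWING_POINTS) / SWING_POINTS
    grid = np.concatenate([stance_grid, swing_grid])
    V = np.empty((seg.shape[0], N_POINTS))
    for m in range(seg.shape[0]):
        V[m] = np.interp(grid, t, seg[m])
    return NormalizedCycle(V=V, cycle_index=cycle_index, muscle_labels=muscle_labels)


def segment_cycles(
    envelopes: np.ndarray,
    fs: float,
    touchdowns: np.ndarray,
    liftoffs: np.ndarray,
    segment_start: float = 0.0,
    muscle_labels=MUSCLE_LABELS,
) -> list[NormalizedCycle]:
    """Cut a trial's envelopes into time-normalized cycles.

    One cycle per consecutive touchdown pair; requires one lift-off inside
    each pair (see :mod:`syngait.events`).
    """
    cycles = []
    for i in range(len(touchdowns) - 1):
        cycles.append(
            time_normalize_cycle(
                envelopes,
                fs,
                touchdowns[i],
                liftoffs[i],
                touchdowns[i + 1],
                segment_start=segment_start,
                cycle_index=i,
                muscle_labels=muscle_labels,
            )
        )
    return cycles
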
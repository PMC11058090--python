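"""Gait-event detection from a foot-mounted 3-axis accelerometer.

Touchdown: per gait cycle, locate the minimum of the (15 Hz low-pass
filtered) vertical acceleration, open a window from 150 ms before to
100 ms after it, and take the characteristic maximum of the vertical
acceleration inside that window as the touchdown instant.

Lift-off: for each consecutive touchdown pair, restrict the
anteroposterior acceleration to the window from 300 ms after the first
touchdown to 200 ms before the next one and take its minimum; a +3 ms
correction (the detector's mean bias against force-plate ground truth)
is added by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .emg import zero_phase_filter

__all__ = [
    "AccelTrace",
    "GaitEvents",
    "detect_touchdowns",
    "detect_liftoffs",
    "detect_events",
    "temporal_parameters",
    "coefficient_of_variation",
]

LIFTOFF_CORRECTION_S = 0.003
ACCEL_LP_CUTOFF_HZ = 15.0


@dataclass
class AccelTrace:
    """3-axis foot acceleration (m s^-2) at sampling rate ``fs`` (Hz)."""

    fs: float
    vertical: np.ndarray
    anteroposterior: np.ndarray
    mediolateral: np.ndarray

    def __post_init__(self) -> None:
        self.vertical = np.asarray(self.vertical, dtype=float)
        self.anteroposterior = np.asarray(self.anteroposterior, dtype=float)
        self.mediolateral = np.asarray(self.mediolateral, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got fs={self.fs}")
        n = len(self.vertical)
        if len(self.anteroposterior) != n or len(self.mediolateral) != n:
            raise ValueError("accelerometer axes must have equal lengths")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.vertical)) / self.fs


@dataclass
class GaitEvents:
    """Strictly interleaved touchdown/lift-off times in seconds.

    With k touchdowns there are k-1 lift-offs, one per complete cycle, and
    td_i < lo_i < td_{i+1} for every cycle i.
    """

    touchdowns: np.ndarray
    liftoffs: np.ndarray

    def __post_init__(self) -> None:
        self.touchdowns = np.asarray(self.touchdowns, dtype=float)
        self.liftoffs = np.asarray(self.liftoffs, dtype=float)
        if len(self.liftoffs) != len(self.touchdowns) - 1:
            raise ValueError(
                f"{len(self.touchdowns)} touchdowns require "
                f"{len(self.touchdowns) - 1} lift-offs, got {len(self.liftoffs)}"
            )
        td, lo = self.touchdowns, self.liftoffs
        ok = (td[:-1] < lo) & (lo < td[1:])
        if not np.all(ok):
            bad = int(np.nonzero(~ok)[0][0])
            raise ValueError(
                f"events not interleaved at cycle {bad}: "
                f"td={td[bad]:.4f}, lo={lo[bad]:.4f}, next td={td[bad + 1]:.4f}"
            )

    @property
    def n_cycles(self) -> int:
        return len(self.liftoffs)


def _lowpass(trace: AccelTrace, prefiltered: bool) -> tuple[np.ndarray, np.ndarray]:
    if prefiltered:
        return trace.vertical, trace.anteroposterior
    v = zero_phase_filter(trace.vertical, trace.fs, ACCEL_LP_CUTOFF_HZ, "lowpass")
    ap = zero_phase_filter(trace.anteroposterior, trace.fs, ACCEL_LP_CUTOFF_HZ, "lowpass")
    return v, ap


def detect_touchdowns(
    trace: AccelTrace,
    prefiltered: bool = False,
    min_cycle_s: float = 0.6,
) -> np.ndarray:
    """Detect touchdown times from vertical foot acceleration.

    Candidate cycles are vertical-acceleration minima separated by at least
    ``min_cycle_s``; within the -150/+100 ms window around each minimum the
    sample of maximal vertical acceleration is returned. A trace without
    detectable cycles yields an empty array with a warning.
    """
    v, _ = _lowpass(trace, prefiltered)
    fs = trace.fs
    span = float(np.ptp(v))
    if span <= 0:
        warnings.warn("no gait cycles detectable in a constant vertical trace")
        return np.array([])
    minima, _ = signal.find_peaks(
        -v, distance=max(1, int(round(min_cycle_s * fs))), prominence=0.25 * span
    )
    if minima.size == 0:
        warnings.warn("no gait cycles detectable in vertical acceleration")
        return np.array([])
    tds = []
    for idx in minima:
        a = max(0, idx - int(round(0.150 * fs)))
        b = min(len(v), idx + int(round(0.100 * fs)) + 1)
        tds.append(a + int(np.argmax(v[a:b])))
    return np.unique(tds) / fs


def detect_liftoffs(
    trace: AccelTrace,
    touchdowns: np.ndarray,
    prefiltered: bool = False,
    correction_s: float = LIFTOFF_CORRECTION_S,
) -> np.ndarray:
    """Detect one lift-off per consecutive touchdown pair.

    The anteroposterior minimum is searched in [td + 300 ms, td_next - 200 ms];
    ``correction_s`` (default +3 ms) is added to each detected time. Cycles too
    short to hold the window are skipped with a warning; the trailing touchdown
    has no successor and emits no lift-off.
    """
    _, ap = _lowpass(trace, prefiltered)
    fs = trace.fs
    touchdowns = np.asarray(touchdowns, dtype=float)
    los = []
    for i in range(len(touchdowns) - 1):
        a = int(round((touchdowns[i] + 0.300) * fs))
        b = int(round((touchdowns[i + 1] - 0.200) * fs)) + 1
        a = max(a, 0)
        b = min(b, len(ap))
        if b <= a:
            warnings.warn(
                f"cycle {i} shorter than 0.5 s: lift-off window empty, cycle skipped"
            )
            continue
        los.append((a + int(np.argmin(ap[a:b]))) / fs + correction_s)
    return np.asarray(los)


def detect_events(trace: AccelTrace, prefiltered: bool = False, **kwargs) -> GaitEvents:
    """Run both detectors and return validated, interleaved events."""
    v, ap = _lowpass(trace, prefiltered)
    filt = AccelTrace(trace.fs, v, ap, trace.mediolateral)
    tds = detect_touchdowns(filt, prefiltered=True, **kwargs)
    los = detect_liftoffs(filt, tds, prefiltered=True)
    return GaitEvents(touchdowns=tds, liftoffs=los)


def temporal_parameters(events: GaitEvents) -> pd.DataFrame:
    """Per-cycle stance/swing times, cadence and duty factor.

    t_st = lo - td, t_sw = td_next - lo, cadence = 2*60 / (t_st + t_sw)
    (two steps per gait cycle, in steps per minute) and
    duty_factor = t_st / (t_st + t_sw).
    """
    td, lo = events.touchdowns, events.liftoffs
    t_st = lo - td[:-1]
    t_sw = td[1:] - lo
    cycle_time = t_st + t_sw
    return pd.DataFrame(
        {
            "cycle": np.arange(events.n_cycles),
            "t_st": t_st,
            "t_sw": t_sw,
            "cadence": 120.0 / cycle_time,
            "duty_factor": t_st / cycle_time,
        }
    )


def coefficient_of_variation(values) -> float:
    """Sample standard deviation divided by the mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("coefficient of variation needs at least 2 values")
    mean = float(np.mean(x))
    if mean == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(np.std(x, ddof=1) / mean)
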
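"""Seeded synthetic gait-EMG generator with known ground truth.

The generator emulates the structure of a perturbed-walking trial: 13
lower-limb muscles, gait cycles time-normalized to 200 points (100 stance +
100 swing), and four phase-locked fundamental synergies — weight acceptance,
propulsion, early swing and late swing. A trial is a series of 12 cycles:
three unperturbed cycles, the perturbed cycle, and eight recovery cycles.

Activation-pattern prototypes are circular von Mises bumps
``exp(kappa * (cos(theta - mu) - 1))`` so that synergies near the cycle
boundary wrap correctly; the perturbation is planted as a circular shift of
the bump centers (a center-of-activity shift, in radians) and a controlled
widening of the bumps (a multiplicative factor on their full width at half
maximum), both decaying geometrically over the recovery cycles.

Every stochastic operation takes its seed from the spec; there is no global
random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .emg import N_POINTS, EmgTrial, NormalizedCycle, zero_phase_filter
from .events import AccelTrace, GaitEvents
from .muscles import MUSCLE_LABELS

__all__ = [
    "Prototype",
    "SynergySpec",
    "GroundTruth",
    "default_prototypes",
    "generate_synergy_prototypes",
    "synthesize_trial",
    "synthesize_raw_signals",
]


@dataclass(frozen=True)
class Prototype:
    """One fundamental-synergy template.

    ``phase_center`` is the bump center as a fraction of the gait cycle in
    [0, 1); ``concentration`` the von Mises kappa (larger = narrower);
    ``dominant_muscles`` the codes receiving weights near 1.
    """

    label: str
    phase_center: float
    concentration: float
    dominant_muscles: tuple[str, ...]


def default_prototypes() -> tuple[Prototype, ...]:
    """Four fundamental synergies at conventional gait-phase placements.

    Weight acceptance (knee extensors and glutei) early in stance, propulsion
    (plantar flexors) in late stance, early swing (foot dorsiflexors and hip
    flexor) just after lift-off, late swing (knee flexors) before the next
    touchdown.
    """
    return (
        Prototype("weight_acceptance", 0.10, 5.0, ("ME", "MA", "RF", "VM", "VL")),
        Prototype("propulsion", 0.40, 5.0, ("PL", "GM", "GL", "SO")),
        Prototype("early_swing", 0.60, 5.0, ("TA", "FL")),
        Prototype("late_swing", 0.90, 5.0, ("ST", "BF")),
    )


@dataclass
class SynergySpec:
    """Full description of a synthetic trial.

    ``perturbed_cycle_index`` defaults to 3 (0-based), i.e. the fourth cycle:
    three unperturbed cycles, the perturbed one, then recovery cycles.
    ``coa_shift`` (radians) and ``widen_factor`` (>= 1, multiplies the
    prototype FWHM) are applied at the perturbed cycle and decay geometrically
    (factor ``recovery_decay`` per cycle) over ``n_recovery`` recovery cycles.
    ``noise_sd`` is the standard deviation of the zero-truncated additive
    Gaussian amplitude noise, in units of the unit-normalized activation.
    ``stance_s``/``swing_s`` set the real-time cycle layout used when raw
    signals are synthesized.
    """

    n_muscles: int = 13
    n_points: int = N_POINTS
    prototypes: tuple[Prototype, ...] = field(default_factory=default_prototypes)
    noise_sd: float = 0.05
    n_cycles: int = 12
    perturbed_cycle_index: int = 3
    coa_shift: float = 0.0
    widen_factor: float = 1.0
    n_recovery: int = 4
    recovery_decay: float = 0.5
    stance_s: float = 0.7
    swing_s: float = 0.4
    muscle_labels: tuple[str, ...] = MUSCLE_LABELS
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [p.label for p in self.prototypes]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate prototype labels: {labels}")
        for p in self.prototypes:
            if not (0.0 <= p.phase_center < 1.0):
                raise ValueError(
                    f"phase_center of {p.label!r} must be in [0, 1), got {p.phase_center}"
                )
            if p.concentration <= 0:
                raise ValueError(f"concentration of {p.label!r} must be positive")
            unknown = set(p.dominant_muscles) - set(self.muscle_labels)
            if unknown:
                raise ValueError(f"unknown dominant muscles for {p.label!r}: {unknown}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")
        if self.widen_factor < 1:
            raise ValueError(f"widen_factor must be >= 1, got {self.widen_factor}")
        if self.n_muscles != len(self.muscle_labels):
            raise ValueError("n_muscles must match the number of muscle labels")
        if not (0 <= self.perturbed_cycle_index < self.n_cycles):
            raise ValueError("perturbed_cycle_index outside the trial")

    @property
    def n_synergies(self) -> int:
        return len(self.prototypes)


@dataclass
class GroundTruth:
    """Planted factors and events backing a synthetic trial.

    ``M_true`` is muscles x synergies, ``P_true`` the baseline (unperturbed)
    synergies x points patterns with each row max-normalized to 1;
    ``P_cycles`` holds the per-cycle patterns actually used (shifted/widened
    at and after the perturbation); ``events_true`` the planted
    touchdown/lift-off times when raw signals were synthesized, and
    ``envelopes_true`` the planted real-time EMG envelopes.
    """

    M_true: np.ndarray
    P_true: np.ndarray
    prototypes: tuple[Prototype, ...]
    P_cycles: list[np.ndarray] | None = None
    events_true: GaitEvents | None = None
    envelopes_true: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.min(self.M_true) < 0 or np.min(self.P_true) < 0:
            raise ValueError("ground-truth factors must be non-negative")


def _vonmises_bump(
    n_points: int, phase_center: float, concentration: float
) -> np.ndarray:
    theta = 2.0 * np.pi * np.arange(n_points) / n_points
    mu = 2.0 * np.pi * phase_center
    bump = np.exp(concentration * (np.cos(theta - mu) - 1.0))
    return bump / bump.max()


def _widen_concentration(concentration: float, widen_factor: float) -> float:
    """Concentration whose bump FWHM is ``widen_factor`` times the original.

    For ``exp(kappa*(cos(d)-1))`` the half-maximum sits at
    d = arccos(1 - ln2/kappa); widening scales d and inverts the relation.
    """
    if widen_factor == 1.0:
        return concentration
    arg = 1.0 - math.log(2.0) / concentration
    if arg <= -1.0:
        return concentration  # bump already wider than the whole cycle
    d = math.acos(arg)
    d_new = min(widen_factor * d, math.pi - 1e-6)
    return math.log(2.0) / (1.0 - math.cos(d_new))


def generate_synergy_prototypes(spec: SynergySpec) -> GroundTruth:
    """Build the planted factors M_true (muscles x p) and P_true (p x points).

    Pattern rows are unimodal circular bumps max-normalized to 1. Dominant
    muscles draw weights from U(0.85, 1), all others from U(0.02, 0.10);
    deterministic for a fixed spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.n_synergies
    P = np.vstack(
        [
            _vonmises_bump(spec.n_points, proto.phase_center, proto.concentration)
            for proto in spec.prototypes
        ]
    )
    M = rng.uniform(0.02, 0.10, size=(spec.n_muscles, p))
    label_index = {lab: i for i, lab in enumerate(spec.muscle_labels)}
    for j, proto in enumerate(spec.prototypes):
        for lab in proto.dominant_muscles:
            M[label_index[lab], j] = rng.uniform(0.85, 1.0)
    return GroundTruth(M_true=M, P_true=P, prototypes=spec.prototypes)


def _perturbation_schedule(spec: SynergySpec) -> list[tuple[float, float]]:
    """Per-cycle (coa_shift, widen_factor) after geometric recovery decay."""
    sched = []
    for c in range(spec.n_cycles):
        k = c - spec.perturbed_cycle_index
        if k < 0 or k > spec.n_recovery:
            sched.append((0.0, 1.0))
        else:
            g = spec.recovery_decay**k
            sched.append((spec.coa_shift * g, 1.0 + (spec.widen_factor - 1.0) * g))
    return sched


def _cycle_patterns(spec: SynergySpec, shift: float, widen: float) -> np.ndarray:
    rows = []
    for proto in spec.prototypes:
        center = (proto.phase_center + shift / (2.0 * np.pi)) % 1.0
        kappa = _widen_concentration(proto.concentration, widen)
        rows.append(_vonmises_bump(spec.n_points, center, kappa))
    return np.vstack(rows)


def synthesize_trial(
    spec: SynergySpec,
) -> tuple[list[NormalizedCycle], GroundTruth]:
    """Generate the per-cycle V matrices of one trial.

    Each cycle's matrix is ``M_true @ P_cycle`` plus zero-truncated Gaussian
    amplitude noise; cycles at and after the perturbed cycle use shifted and
    widened prototypes per the recovery schedule. Reproducible for a fixed
    spec seed.
    """
    gt = generate_synergy_prototypes(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    cycles: list[NormalizedCycle] = []
    P_cycles: list[np.ndarray] = []
    for c, (shift, widen) in enumerate(_perturbation_schedule(spec)):
        P_c = gt.P_true if (shift == 0.0 and widen == 1.0) else _cycle_patterns(spec, shift, widen)
        V = gt.M_true @ P_c
        if spec.noise_sd > 0:
            V = np.maximum(V + rng.normal(0.0, spec.noise_sd, size=V.shape), 0.0)
        cycles.append(
            NormalizedCycle(V=V, cycle_index=c, muscle_labels=spec.muscle_labels)
        )
        P_cycles.append(P_c)
    gt.P_cycles = P_cycles
    return cycles, gt


def _snap(t: float, fs: float) -> float:
    return round(t * fs) / fs


def synthesize_raw_signals(
    spec: SynergySpec,
    fs_emg: float = 2000.0,
    fs_accel: float = 143.0,
    pad_s: float = 0.5,
    carrier_band: tuple[float, float] = (80.0, 350.0),
) -> tuple[EmgTrial, AccelTrace, GaitEvents, GroundTruth]:
    """Synthesize raw EMG and foot-acceleration traces for one trial.

    Raw EMG per muscle is band-limited Gaussian noise amplitude-modulated by
    the muscle's planted envelope (``M_true @ P_cycle`` mapped back to real
    time via the stance/swing layout). The vertical accelerometer axis
    carries a sharp impact transient at each touchdown preceded by a deep
    minimum, and the anteroposterior axis a clear minimum at each lift-off,
    so the event detectors can recover the planted times. Planted events are
    snapped to the accelerometer sample grid and returned as ground truth.
    """
    if fs_emg < 500:
        raise ValueError(f"fs_emg must be >= 500 Hz, got {fs_emg}")
    if fs_accel < 50:
        raise ValueError(f"fs_accel must be >= 50 Hz, got {fs_accel}")
    cycle_s = spec.stance_s + spec.swing_s
    if spec.stance_s * fs_accel < 2 or spec.swing_s * fs_accel < 2:
        raise ValueError("stance/swing durations not representable at fs_accel")
    if not (0.3 + 2 / fs_accel < spec.stance_s < cycle_s - 0.2 - 2 / fs_accel):
        raise ValueError(
            f"stance_s={spec.stance_s} leaves no lift-off search window inside "
            f"a {cycle_s:.3f} s cycle at fs_accel={fs_accel} Hz"
        )

    cycles, gt = synthesize_trial(spec)
    tds = np.array(
        [_snap(pad_s + k * cycle_s, fs_accel) for k in range(spec.n_cycles + 1)]
    )
    los = np.array(
        [_snap(td + spec.stance_s, fs_accel) for td in tds[:-1]]
    )
    events = GaitEvents(touchdowns=tds, liftoffs=los)

    duration = tds[-1] + pad_s
    n_emg = int(round(duration * fs_emg))
    t_emg = np.arange(n_emg) / fs_emg

    # knot times of the 200-point grid mapped to real time, per cycle
    knot_t = []
    for k in range(spec.n_cycles):
        td, lo, td_next = tds[k], los[k], tds[k + 1]
        st = td + (lo - td) * np.arange(100) / 100.0
        sw = lo + (td_next - lo) * np.arange(100) / 100.0
        knot_t.append(np.concatenate([st, sw]))
    knot_t = np.concatenate(knot_t + [np.array([tds[-1]])])

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    env = np.zeros((spec.n_muscles, n_emg))
    raw = np.zeros((spec.n_muscles, n_emg))
    E_cycles = np.stack([gt.M_true @ P for P in gt.P_cycles])  # cycles x m x 200
    for m in range(spec.n_muscles):
        knot_v = np.concatenate(
            [E_cycles[k, m] for k in range(spec.n_cycles)] + [E_cycles[-1, m, :1]]
        )
        e = np.interp(t_emg, knot_t, knot_v, left=0.0, right=0.0)
        carrier = rng.standard_normal(n_emg)
        carrier = zero_phase_filter(carrier, fs_emg, list(carrier_band), "bandpass")
        carrier /= np.mean(np.abs(carrier))
        env[m] = e
        raw[m] = e * carrier
    trial = EmgTrial(samples=raw, fs=fs_emg, muscle_labels=spec.muscle_labels)

    n_acc = int(round(duration * fs_accel))
    t_acc = np.arange(n_acc) / fs_accel
    vert = np.zeros(n_acc)
    ap = np.zeros(n_acc)
    ml = 0.5 * np.sin(2.0 * np.pi * t_acc / cycle_s)
    for td in tds:
        vert += 30.0 * np.exp(-0.5 * ((t_acc - td) / 0.015) ** 2)
        vert -= 25.0 * np.exp(-0.5 * ((t_acc - (td - 0.060)) / 0.025) ** 2)
    for td, lo in zip(tds[:-1], los):
        ap -= 10.0 * np.exp(-0.5 * ((t_acc - lo) / 0.030) ** 2)
        ap += 3.0 * np.exp(-0.5 * ((t_acc - (td + 0.10)) / 0.040) ** 2)
    trace = AccelTrace(fs=fs_accel, vertical=vert, anteroposterior=ap, mediolateral=ml)

    gt.events_true = events
    gt.envelopes_true = env
    return trial, trace, events, gt
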
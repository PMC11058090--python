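"""EMG conditioning: filter chain, amplitude and time normalization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from syngait import (
    EmgTrial,
    SynergySpec,
    normalize_amplitude,
    preprocess_emg,
    synthesize_raw_signals,
    time_normalize_cycle,
)
from syngait.emg import zero_phase_filter


def make_trial(samples, fs=2000.0):
    samples = np.atleast_2d(samples)
    labels = tuple(f"m{i}" for i in range(samples.shape[0]))
    return EmgTrial(samples=samples, fs=fs, muscle_labels=labels)


class TestPreprocess:
    def test_dc_channel_maps_to_zero_envelope(self):
        trial = make_trial(np.full((1, 4000), 3.7))
        env = preprocess_emg(trial)
        assert np.max(env.samples) < 1e-6

    def test_envelope_is_non_negative(self, rng):
        trial = make_trial(rng.standard_normal((3, 4000)))
        assert np.min(preprocess_emg(trial).samples) >= 0

    def test_zero_phase_symmetric_burst_keeps_peak_position(self, rng):
        fs = 2000.0
        t = np.arange(8000) / fs
        burst = np.exp(-0.5 * ((t - 2.0) / 0.05) ** 2)
        x = burst * np.sign(np.sin(2 * np.pi * 150 * t))
        env = preprocess_emg(make_trial(x, fs)).samples[0]
        assert abs(int(np.argmax(env)) - int(np.argmax(burst))) <= 2

    def test_envelope_tracks_planted_modulation(self):
        trial, _, _, gt = synthesize_raw_signals(SynergySpec(seed=12))
        env = preprocess_emg(trial)
        for m in range(trial.n_muscles):
            r = np.corrcoef(env.samples[m], gt.envelopes_true[m])[0, 1]
            assert r > 0.95

    def test_low_sampling_rate_rejected_naming_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess_emg(make_trial(np.zeros((1, 100)), fs=120.0))

    def test_lowpass_stage_idempotent_in_band(self):
        # a signal well inside the 20 Hz envelope passband barely changes
        # on a second application of the low-pass stage
        fs = 2000.0
        t = np.arange(8000) / fs
        x = 1.0 + 0.5 * np.sin(2 * np.pi * 2.0 * t)
        once = zero_phase_filter(x, fs, 20.0, "lowpass")
        twice = zero_phase_filter(once, fs, 20.0, "lowpass")
        rms = np.sqrt(np.mean((twice - once) ** 2)) / np.sqrt(np.mean(once**2))
        assert rms < 0.01


class TestAmplitudeNormalization:
    def test_full_span_maps_to_unit_interval(self):
        env = np.linspace(0.2, 1.2, 500)[None, :]
        out = normalize_amplitude(env, ("TA",))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_cycle_below_trial_max_keeps_submaximal_peak(self):
        # two concatenated cycles; the first peaks at half the trial max
        cycle1 = 0.5 * np.sin(np.linspace(0, np.pi, 100))
        cycle2 = 1.0 * np.sin(np.linspace(0, np.pi, 100))
        out = normalize_amplitude(np.concatenate([cycle1, cycle2])[None, :], ("TA",))
        assert out[0, :100].max() == pytest.approx(0.5, abs=1e-6)
        assert out[0, 100:].max() == pytest.approx(1.0)

    def test_constant_channel_raises_naming_muscle(self):
        env = np.vstack([np.linspace(0, 1, 50), np.full(50, 0.3)])
        with pytest.raises(ValueError, match="MA"):
            normalize_amplitude(env, ("ME", "MA"))

    @given(
        a=st.floats(0.1, 50.0),
        b=st.floats(-10.0, 10.0),
    )
    def test_invariant_to_affine_rescaling(self, a, b):
        x = np.sin(np.linspace(0, 7, 300))[None, :]
        base = normalize_amplitude(x, ("TA",))
        scaled = normalize_amplitude(a * x + b, ("TA",))
        assert np.allclose(base, scaled, atol=1e-9)


class TestTimeNormalization:
    fs = 2000.0

    def seg(self, f, t_end=1.2):
        t = np.arange(int(t_end * self.fs)) / self.fs
        return f(t), t

    def test_grid_is_200_points_with_100_100_split(self):
        x, t = self.seg(lambda t: t)
        cyc = time_normalize_cycle(x[None, :], self.fs, 0.0, 0.7, 1.1,
                                   muscle_labels=("TA",))
        assert cyc.n_points == 200
        assert cyc.stance_points == 100 and cyc.swing_points == 100
        # stance/swing boundary: point 100 sits exactly at lift-off
        assert cyc.V[0, 100] == pytest.approx(0.7, abs=1e-3)
        assert cyc.V[0, 0] == pytest.approx(0.0, abs=1e-6)

    def test_linear_signal_stays_linear_within_each_phase(self):
        x, t = self.seg(lambda t: 2.0 * t + 0.5)
        cyc = time_normalize_cycle(x[None, :], self.fs, 0.0, 0.7, 1.1,
                                   muscle_labels=("TA",))
        stance = cyc.V[0, :100]
        swing = cyc.V[0, 100:]
        assert np.allclose(np.diff(stance, 2), 0.0, atol=1e-9)
        assert np.allclose(np.diff(swing, 2), 0.0, atol=1e-9)

    def test_constant_signal_stays_constant(self):
        x, _ = self.seg(lambda t: np.full_like(t, 0.42))
        cyc = time_normalize_cycle(x[None, :], self.fs, 0.0, 0.7, 1.1,
                                   muscle_labels=("TA",))
        assert np.allclose(cyc.V, 0.42)

    def test_round_trip_reproduces_samples_at_original_times(self):
        td, lo, ntd = 0.0, 0.7, 1.1
        x, t = self.seg(lambda t: 0.5 + 0.4 * np.sin(2 * np.pi * 1.5 * t))
        cyc = time_normalize_cycle(x[None, :], self.fs, td, lo, ntd,
                                   muscle_labels=("TA",))
        stance_grid = td + (lo - td) * np.arange(100) / 100
        swing_grid = lo + (ntd - lo) * np.arange(100) / 100
        grid = np.concatenate([stance_grid, swing_grid])
        # invert: interpolate the normalized cycle back onto sample times
        inside = (t >= td) & (t < ntd - 0.01)
        back = np.interp(t[inside], grid, cyc.V[0])
        assert np.allclose(back, x[inside], atol=5e-4)

    def test_events_out_of_order_rejected(self):
        x, _ = self.seg(lambda t: t)
        with pytest.raises(ValueError, match="out of order"):
            time_normalize_cycle(x[None, :], self.fs, 0.7, 0.2, 1.1)

    def test_too_short_phase_rejected(self):
        x = np.linspace(0, 1, 300)[None, :]
        with pytest.raises(ValueError, match="too short"):
            time_normalize_cycle(x, 200.0, 0.0, 0.004, 1.0, muscle_labels=("TA",))
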
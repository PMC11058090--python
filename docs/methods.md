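# Methods

## The model

A trial of walking yields, per gait cycle, a non-negative matrix
**V** (m × n; m = 13 muscles, n = 200 normalized time points). The synergy
model approximates **V** ≈ **V**_R = **MP**, where **M** (m × p) holds
time-invariant, non-negative muscle weights and **P** (p × n) non-negative
activation patterns. p is the number of synergies; during steady and
perturbed walking four fundamental synergies — weight acceptance, propulsion,
early swing and late swing — typically suffice. The perturbation response is
quantified per cycle and synergy by three metrics relative to a reference
cycle: cosine similarity (CS) of weights and patterns, the full width at half
maximum (FWHM) of the pattern, and its center of activity (CoA).

## Signal conditioning

Raw EMG (nominal 2 kHz; the acquisition device's 10–500 Hz band-pass is
assumed already applied, and synthetic raw EMG is generated band-limited) is
high-pass filtered at 50 Hz, full-wave rectified, and low-pass filtered at
20 Hz. "4th-order zero-phase Butterworth" is implemented as a 4th-order
design applied forward-backward (`sosfiltfilt`), i.e. an effective 8th-order
magnitude response with exactly zero phase; we take this as the most literal
reading — the alternative (halving the design order so the *effective* order
is 4) changes only the roll-off steepness, not any contract tested here. The
envelope is clipped at zero: the low-pass of a rectified signal can
undershoot by a ripple of order 1e-3, and every downstream stage requires
non-negativity.

Amplitude normalization maps each muscle to [0, 1] using the min/max over the
*whole trial* (all 12 consecutive cycles), so a cycle whose local peak is
submaximal keeps a peak < 1 — this preserves between-cycle amplitude
differences, which the perturbation metrics rely on. A constant channel is a
hard error naming the muscle, never silent zeros.

Time normalization resamples each cycle by piecewise-linear interpolation
onto a half-open 200-point grid: point 0 at touchdown, points 0–99 spanning
stance, 100–199 spanning swing, the next touchdown excluded so consecutive
cycles share no sample. Linear interpolation is the simplest scheme
consistent with the fixed-grid contract; it preserves affine signals exactly
within each phase.

## Gait events

The accelerometer chain low-pass filters all axes at 15 Hz (4th-order
zero-phase Butterworth) unless the caller marks the trace as pre-filtered.
Cycle discovery — which the touchdown rule presumes but does not define — is
peak-picking of vertical-acceleration minima separated by ≥ 0.6 s with a
prominence floor of 25% of the trace's range; both are configurable, and the
values are conventional for walking cadences. Touchdown is the global maximum
of vertical acceleration inside the −150/+100 ms window around each minimum
("characteristic maximum" is read as the in-window global maximum; local-
maximum heuristics would only matter for multi-peaked impact shapes the
generator does not produce). Lift-off is the anteroposterior minimum in
[td + 300 ms, td_next − 200 ms] plus a +3 ms bias correction; the correction
is a configurable constant (default on) so the uncorrected detector remains
testable. Cycles too short for the window are skipped with a warning, and
detected events must satisfy td_i < lo_i < td_{i+1} — violations raise rather
than silently reorder.

Temporal parameters per cycle: t_st = lo − td, t_sw = td_next − lo,
duty factor = t_st/(t_st + t_sw), and cadence = 2·60/(t_st + t_sw) steps per
minute — two steps per gait cycle, the conventional reading of "steps per
minute". The coefficient of variation is the sample SD over the mean.

## Factorization

Multiplicative updates for the squared-Frobenius objective:

    P ← P ∘ (MᵀV) ⊘ (MᵀMP),   M ← M ∘ (VPᵀ) ⊘ (MPPᵀ),

with a 1e-12 denominator guard. Both factors initialize uniform on (0, 1],
seeded per repetition. Convergence: stop when R² (1 − SSE/SST around the
grand mean) improves by less than 1e-4 over the last 20 iterations, hard cap
1000 iterations. The error sequence is non-increasing (asserted in tests to
1e-10, the slack covering the denominator guard).

Per cycle the factorization is repeated 20 times; repetitions are aligned to
the first by optimal one-to-one assignment (Hungarian algorithm) on the
cosine similarity of muscle-weight columns — greedy matching above rank 8,
where assignment cost is irrelevant for this package's ranks — then averaged.
Plain averaging without matching would mix permuted components; "averaging"
is therefore read as matching-then-averaging. Output convention: each pattern
row is scaled to max 1 with the inverse scale folded into the matching weight
column, so **MP** is unchanged; max-normalized weights are additionally
available for display.

Rank selection computes, for each candidate rank 1..10, the best R² over 10
seeded repetitions, then picks the smallest rank from which an ordinary
least-squares line fits the remaining curve with mean squared residual below
1e-4. This mirrors the curve-flattening logic used for the cluster count
(below) with a tighter threshold suited to the ~[0.1, 1] range of R² curves;
10 repetitions suffice here because only the per-rank *maximum* enters the
curve, while the per-cycle extraction keeps the full 20. Both the threshold
and the repetition count are exposed in configuration.

## Classification

Activation patterns pooled over cycles (and, in multi-subject use,
participants) are max-normalized — classification is amplitude-invariant —
and clustered with k-means (scikit-learn, 10 seeded restarts, squared
Euclidean distance) for k = 1..13, one candidate per recorded muscle. The WSS
(inertia) curve is normalized by the total sum of squares before the elbow
test, making the MSE < 10⁻³ threshold scale-free; an absolute threshold
would silently depend on the pooled sample size. The chosen k is the smallest
from which the normalized curve fits a least-squares line with MSE below the
threshold.

With exactly four clusters, labels follow ascending centroid CoA from stance
onset: weight acceptance < propulsion < early swing < late swing. With any
other k, each fundamental label goes to the cluster whose centroid CoA is
circularly closest to the label's canonical phase (0.10, 0.40, 0.60, 0.90 of
the cycle); leftover clusters are non-classifiable, with a warning.

A pattern is *fundamental* when it has exactly one main activation peak:
after a 5-point circular moving average, circular local maxima reaching
≥ 50% of the global maximum and separated by ≥ 20 of 200 points are counted.
Patterns failing this, or with cosine similarity < 0.75 to their assigned
centroid, are non-classifiable; their fraction is always reported, and their
metric rows are emitted as NaN sentinels rather than dropped.

## Metrics

CS = A·B/(‖A‖‖B‖), clamped to [−1, 1] against one-ulp rounding overshoot (so
CS of a vector with itself is exactly 1). FWHM is the *count* of points whose
min-subtracted value strictly exceeds half the min-subtracted maximum — a
point count, deliberately not the contiguous-interval definition, so split
peaks accumulate. CoA maps point i to angle θᵢ = 2πi/200 with θ = 0 at
touchdown (the convention adopted here; only the [0, 2π) range is inherent to
the definition) and returns atan2(Σaᵢ sinθᵢ, Σaᵢ cosθᵢ) in [0, 2π); a
vanishing resultant (uniform pattern) yields NaN with a warning.

The similarity series uses the first cycle of the series — the third cycle
before the perturbation, the one most remote from it — as reference.
Synergies are matched across cycles by their classification labels when
available, otherwise by optimal cosine assignment of weight columns against
the reference.

## Statistics

Cohen's d uses sample (n−1) variances in the pooled SD; magnitude classes:
|d| < 0.2 none, < 0.5 small, < 0.8 moderate, ≥ 0.8 large.
Benjamini–Hochberg adjustment is delegated to statsmodels and cross-checked
against a brute-force step-up enumeration in tests. Mixed-effects models and
statistical parametric mapping are deliberately not reimplemented — they are
off-the-shelf analyses consuming the tidy tables this package exports. The
pipeline's built-in contrast (perturbed + recovery cycles vs the unperturbed
baseline, per synergy and metric, Welch t-test + d + BH) is a convenience
summary whose grouping is a config choice, not a claim about the right
mixed-model structure.

## Synthetic data: what it emulates, and what it does not

Prototypical activation patterns are von Mises bumps
exp(κ(cos(θ − μ) − 1)), max-normalized, κ = 5 by default (FWHM ≈ 34 of 200 points, in the
range typical of locomotor primitives), centered at 0.10/0.40/0.60/0.90 of
the cycle — stance/swing placements conventional for the four fundamental
synergies, not measured values. Dominant muscles (knee extensors + glutei;
plantar flexors; dorsiflexors + tensor fasciae latae; knee flexors) draw
weights from U(0.85, 1), all others U(0.02, 0.10). Amplitude noise is
additive Gaussian truncated at zero (default sd 0.05 of the unit-normalized
activation; no published SNR exists for this protocol, so this is a free
parameter chosen to be clearly visible yet far from swamping the signal).
The planted perturbation shifts bump centers by `coa_shift` radians and
multiplies their FWHM by `widen_factor` (the concentration is re-derived so
the FWHM scaling is exact), decaying by 0.5 per cycle over 4 recovery cycles
— consistent with perturbation effects lasting several recovery steps.

Raw signals: EMG is band-limited Gaussian noise (80–350 Hz) amplitude-
modulated by the planted envelope mapped to a 0.7 s stance / 0.4 s swing
layout (cadence ≈ 109 steps/min); the carrier is scaled so that
rectify-and-low-pass of the unit carrier has mean 1, making the planted
envelope the oracle for the conditioning chain. The accelerometer vertical
axis carries a +30 m s⁻² impact Gaussian (sd 15 ms) at each touchdown
preceded by a −25 m s⁻² minimum 60 ms earlier; the anteroposterior axis a
−10 m s⁻² minimum at each lift-off. Event times are snapped to the 143 Hz
grid so sample-exact recovery is well-defined.

What the generator does **not** emulate: inter-muscle crosstalk, motion
artifacts, electrode noise floors, heart-beat contamination, signal-dependent
(multiplicative) noise (available as an option but off by default),
biomechanical coupling between perturbation and kinematics, or between-cycle
variability of event timing. Passing tests therefore demonstrate that the
*pipeline* recovers what was planted under clean, structurally faithful
conditions — not that real recordings would yield identical numbers.

## Numerical choices and degenerate inputs

- Problem sizes: the test suite and acceptance checks run single trials of
  12–30 cycles with 10–20 NMF repetitions — ample for the structural claims
  they verify, and each check completes in seconds.
- NMF on a constant matrix, R² with zero SST, CS with a zero vector, CV with
  zero mean, Cohen's d with zero pooled SD: all hard errors with the cause
  named.
- FWHM of a constant pattern: 0 with a warning. CoA of a zero-resultant
  pattern: NaN with a warning. Flat accelerometer traces: empty event list
  with a warning, not an exception.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; repetition seeds are drawn below 2³¹. Fixed
  seeds give bit-identical generator output and byte-identical pipeline
  tables on rerun.

## Known limitations

- The elbow criteria (rank and cluster count) are threshold rules; on data
  whose R²/WSS curves flatten gradually the selected number is sensitive to
  the threshold, which is why both thresholds are configuration keys and the
  full curves are returned for audit.
- The non-classifiable machinery (similarity floor 0.75, peak rule) uses
  conventional defaults; the real-data fraction of non-classifiable synergies
  depends on rules not fully specifiable from published descriptions, and no
  attempt is made to reproduce any particular rate.
- Single-trial statistics (3 baseline vs 9 perturbed/recovery cycles) have
  little power; the stats stage is a template for the multi-subject case.
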
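# syngait

Muscle-synergy analysis of perturbed treadmill walking.

Human locomotion can be described by a small set of *muscle synergies*: each
synergy couples a time-invariant vector of muscle weights with a
time-dependent activation pattern over the gait cycle. When walking is
perturbed (for example by a sudden treadmill belt shift), the spatiotemporal
structure of these synergies changes — activation patterns shift in time,
widen, and become less similar to unperturbed walking — and recovers over the
following cycles. `syngait` implements the full analysis chain that
quantifies this response, for researchers in neuromotor control and
biomechanics:

- **EMG conditioning** — 4th-order Butterworth zero-phase high-pass at 50 Hz,
  full-wave rectification, 4th-order zero-phase low-pass at 20 Hz; amplitude
  normalization per muscle to the [min, max] of the trial; time normalization
  of each gait cycle to 200 points (100 stance + 100 swing).
- **Gait events from a foot accelerometer** (143 Hz nominal) — touchdown from
  the characteristic vertical-acceleration maximum in a −150/+100 ms window
  around each cycle's vertical minimum; lift-off as the anteroposterior
  minimum in [td + 300 ms, td_next − 200 ms] with a +3 ms bias correction;
  cadence, stance/swing time, duty factor and their coefficient of variation.
- **Synergy extraction** — Gaussian non-negative matrix factorization of each
  cycle's 13 × 200 matrix **V** ≈ **V**_R = **MP**, by multiplicative updates
  minimizing the squared Frobenius error; 20 repetitions component-matched and
  averaged per cycle; reconstruction quality as the coefficient of
  determination R²; the rank p chosen as the smallest rank from which the
  R²-vs-rank curve is flat-linear.
- **Classification** — k-means clustering of activation patterns pooled
  across participants/cycles, the cluster count chosen where the
  within-cluster-sum-of-squares curve fits a line with MSE < 10⁻³; clusters
  labeled weight acceptance, propulsion, early swing, late swing by ascending
  center of activity; synergies without a single main peak are
  non-classifiable.
- **Spatiotemporal metrics** — cosine similarity CS(A, B) = A·B/(‖A‖‖B‖) of
  weights and patterns against a reference (first unperturbed) cycle; FWHM as
  the count of points above half-maximum after min subtraction; center of
  activity (CoA) as the circular first-moment angle θ ∈ [0, 2π) of the
  pattern over the cycle.
- **Statistics** — Cohen's *d* on the pooled SD with the conventional
  small/moderate/large cutoffs, and Benjamini–Hochberg adjustment for the
  post hoc family.

Because no public recordings accompany this kind of protocol, the package
ships a first-class **synthetic-data generator**: seeded trials with four
phase-locked von Mises activation prototypes, amplitude-modulated band-limited
EMG carriers, accelerometer traces with planted impact transients, and a
planted perturbation (CoA shift and FWHM widening decaying geometrically over
recovery cycles) — so every stage of the pipeline can be validated against
known ground truth.

## Worked example

Run the default synthetic experiment (12 cycles, perturbation at cycle 3 with
a −0.3 rad CoA shift and 1.5× FWHM widening, noise sd 0.05):

```python
import pandas as pd
from syngait import run_pipeline

out = run_pipeline(outdir="demo", seed=42)
m = pd.read_csv(out / "metrics.csv")
print(m.groupby("cycle")[["cs_patterns", "fwhm_points"]].mean().round(3))
```

```
       cs_patterns  fwhm_points
cycle
0            1.000       33.250
1            0.991       27.250
2            0.988       33.500
3            0.898       43.250
4            0.965       36.333
5            0.979       29.500
...
11           0.988       31.500
```

Cycle 0 is the reference (CS = 1 by definition). At the perturbed cycle 3 the
mean pattern cosine similarity drops to its minimum (0.898) and the mean FWHM
rises from ~33 to ~43 points — the planted widening — then both recover over
the following cycles. `stats.csv` summarizes the same contrasts as effect
sizes, e.g. `late_swing:cs_patterns  d = -0.96 (large)` with
Benjamini–Hochberg-adjusted p-values.

The same pipeline is scriptable from the shell:

```bash
syngait --seed 42 --outdir demo run-all      # or stage by stage:
syngait --seed 42 --outdir demo simulate
syngait --seed 42 --outdir demo preprocess
...
```

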
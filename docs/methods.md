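# Methods

This note records the model, the numerical conventions, and the design
choices behind `rqalen`, in the order the pipeline runs.

## Delay embedding

A uniformly sampled scalar series is reconstructed as
`X_j = (x_j, x_{j+τ}, …, x_{j+(m−1)τ})`, `j = 1 … N`, `N = n − (m−1)τ`.

* **Lag τ** — the smallest lag at which the normalized autocorrelation
  falls below 1/e. The autocorrelation uses the biased estimator (global
  mean removal, covariance divided by `n`, FFT evaluation); it is standard
  and monotone-safe at small lags. The search window is `n/2` lags. A
  constant series is rejected ("zero variance"). The complementary
  "no decorrelation" guard is retained but is effectively unreachable:
  the biased estimator's lag sums force a crossing below 1/e inside the
  window for every non-constant series.
* **Dimension m** — taken as given, not estimated. Defaults: `m = 3` for
  the Rössler system (its true phase-space dimension), `m = 4` for PPG
  signals (the established choice for near-infrared PPG). Configurable
  everywhere.
* **Norm** — Euclidean throughout, with the maximum norm as an option.
* Indexing is 1-based in formulas; arrays are 0-based internally.

## Recurrence structure

`R_{i,j} = 1` iff `‖X_i − X_j‖ < ε` (strict: ties at exactly ε are
non-recurrent). `ε` is 10% of the attractor diameter, the exact maximum
pairwise distance, computed exhaustively (the exact computation is cheap
at this problem scale; trajectories beyond 60,000 points are rejected
rather than silently approximated).

All four features depend only on the histogram `P(l)` of maximal diagonal
runs, so the full `N × N` matrix is never materialized for production
sizes: a compiled kernel walks each diagonal offset, computes distances on
the fly and run-length-encodes the recurrent cells (O(N) memory). The
explicit matrix implementation exists solely as a small-N verification
oracle, and the test suite checks histogram equality between the two paths
on random trajectories.

Conventions, each of which the tests pin down:

* **Theiler window** — diagonals with offset `|i − j| < theiler` are
  excluded; the default `theiler = 1` removes exactly the line of
  identity. With `theiler = 0` the LOI is counted once, so the
  conservation law `Σ l·P(l) = #recurrent cells outside the excluded
  band` holds for every window.
* **Border lines** — runs touching the matrix border count as lines
  (out-of-range cells are treated as non-recurrent delimiters).
* **Both triangles** — the upper triangle is counted and doubled. All
  ratio measures are invariant to this ×2; raw exported counts are not,
  so the serialized histogram records the convention in its JSON sidecar.

## RQA features

With `l_min = 2` (the smallest length for which "line" is meaningful):

* `DET = Σ_{l≥lmin} l P(l) / Σ_{l≥1} l P(l)` — the denominator includes
  isolated recurrent points deliberately; this asymmetry against L/ENTR
  is part of the definition.
* `Lmax` — largest observed qualifying length; `1/Lmax` is reported as a
  divergence proxy.
* `L = Σ_{l≥lmin} l P(l) / Σ_{l≥lmin} P(l)`.
* `ENTR = −Σ p(l) ln p(l)` in nats, `p(l) = P(l)/N_l`; exactly 0 for a
  single distinct length.
* Undefined measures (empty histogram, or no line reaching `l_min`) are
  explicit nulls with a reason, never 0 — zero is a meaningful entropy.
* `DET > 0.9` as a determinism label is exposed as a flag with a
  configurable threshold, not baked into any computation.

One caution on folklore: a noise-free periodic signal does *not* have
`ENTR ≈ 0` under border-line counting. Its long diagonals are truncated
by the border at distinct lengths, so ENTR grows like the log of the line
count; only a histogram with a single distinct length has zero entropy.
The tests assert the true invariants (DET = 1, long mean line) instead.

## Length scan

Reference measures `S_T` are computed once from a length-`T` prefix
(ideally > 100 average cycles; shorter references trigger a warning).
For each tested length, `n_segments` random start offsets are drawn
without replacement (seeded, reproducible); each segment is embedded and
quantified with the **reference** lag and the **reference** absolute ε.
Re-estimating τ or ε per segment would mix their own sampling noise into
the length effect the scan is trying to isolate. Relative errors
`E_l = |S_l − S_T| / S_T × 100%` are averaged over segments, excluding
(and counting) segments whose measure is undefined.

The minimal length at a threshold is the smallest tested length whose
mean error is at or below the threshold **and stays there at every longer
tested length** — a stable-crossing rule that is conservative and robust
to non-monotone error curves. Limits are reported in points and in
average cycles.

* **Average cycle** — either fixed (PPG convention: 0.8 s per cardiac
  cycle, 327.68 samples at 409.6 Hz) or empirical: mean interval between
  signal peaks (local maxima above the median, separated by at least half
  the dominant period from the autocorrelation's first peak).
* Segments may overlap each other and the reference prefix; both facts
  are recorded in the scan metadata.
* Grids whose floor is below ~3 average cycles warn rather than fail: a
  segment that short cannot contain a separated cycle fragment, but the
  Rössler benchmark protocol itself starts at 1,500 points, which is
  below 3 empirical cycles at the benchmark's sampling density.

## Rössler benchmark

`ẋ = −y − z, ẏ = x + ay, ż = b + z(x − c)` with `a = b = 0.2, c = 5.7`,
integrated by classical RK4 at `dt = 0.001` (1000 Hz), 10,000 transient
steps discarded, `x` decimated by 5 (200 Hz effective), 50,000 output
points by default. The clean output is seed-independent; halving `dt`
while doubling the decimation reproduces the trajectory to integration
tolerance.

**Noise model.** Measurement-style noise is injected into every recorded
sample: `x̃_i = x_i + θ·A·γ_i`, `γ_i ~ U(−1, 1)` seeded, with `A` the
half peak-to-peak amplitude of the clean series, so `θ` is a
noise-to-signal amplitude ratio on `[0, 0.5]`. Two alternatives were
rejected after measurement:

* *Unit-amplitude noise fed back into the integrator each step* is both
  numerically divergent for `θ ≳ 0.3` (per-millisecond kicks random-walk
  `x` past `c`, where the `z` equation amplifies exponentially until
  overflow) and dynamically irrelevant where it survives (kicks of ±0.25
  against a threshold ε ≈ 2.5 leave DET ≈ 0.98).
* *Signal-scale noise fed back* diverges at any injection granularity —
  the random walk it induces in `x` is orders of magnitude faster than
  the flow's mean reversion.

With the adopted convention, DET over the θ grid {0, 0.245, 0.5} falls
0.9999 → ≈0.42 → ≈0.15, strictly decreasing, with mean Lmax ≈ 8 at
θ = 0.5. The alternative normalization `A = max|x|` was measured and
rejected: it misses the mid-grid determinism value by ~14% where the half
peak-to-peak convention lands within ~2%. No linear amplitude convention
can be much steeper in θ without breaking the mid-grid value, which
bounds how far the θ = 0.5 features can drop under this model.

**Sampling density caveat.** At 200 Hz effective sampling the Rössler
orbital period is ≈ 1,173 samples, so consecutive embedded points are
~0.1 units apart — far below ε ≈ 2.5. On the clean signal the
near-diagonal lines therefore never break, `Lmax ≈ N`, and the reference
`L` (≈ 470) and `ENTR` (≈ 6.6) are dominated by these near-LOI lines.
`L` consequently converges slowly with segment length (its error is tied
to the longest lines a segment can hold), while DET is essentially exact
from 1,500 points on. Benchmarks quoting much smaller `Lmax`/`L` at a
nominally identical setup imply a coarser effective sampling or a wider
Theiler window; with the stated integration settings and `theiler = 1`
the values produced here are the self-consistent ones.

## Synthetic PPG generator

The experimental recordings the PPG analysis targets are not publicly
deposited, so a synthetic stand-in reproduces their statistical structure:
beat onsets follow a jittered renewal process (mean cycle 0.8 s, interval
CV 2%, intervals clipped to [0.3, 2]× the mean), each beat adds a
two-Gaussian template (systolic wave: amplitude 1, width 0.09 s, delay
0.18 s; dicrotic wave: 0.35, 0.12 s, 0.45 s) scaled by 3% amplitude
jitter, plus sinusoidal baseline wander (amplitude 0.1, 0.25 Hz,
respiratory band) and white noise (SD 0.01). Defaults: 5 minutes at
409.6 Hz; plain decimation (no anti-alias filter, deliberately, to
emulate sparse acquisition) gives the 204.8/102.4 Hz variants.

The variability and noise levels are set so the generator reproduces the
qualitative RQA signature reported for resting transmission-mode
near-infrared PPG — high determinism at the reference length (DET ≈ 0.95
here vs ≈ 0.998 reported for real recordings) and `Lmax` comparable to
the recording length — while keeping visible beat-to-beat variability.
What the generator does **not** emulate: physiological morphology beyond
the two-wave template, heart-rate drift and autonomic structure in the
interval series, motion artifacts, and sensor optics. Passing tests on
this generator therefore validate the *pipeline* (embedding, recurrence,
error-vs-length behavior, decimation robustness), not clinical
generalizability; real-data reference values (e.g. per-feature minimal
lengths) are expected to differ quantitatively.

## Problem sizes and numerics

Default study conditions: Rössler reference 50,000 points; scans use 100
segments per length (reducible via config); the scripted benchmark scan
tests a grid from 1,500 to 26,000 points (denser below 5,000, where the
DET/L crossings live) plus the 50,000-point anchor, where the error is 0
by construction. PPG scans use a geometric cycle grid 3…152 at three
sampling rates. Distance kernels are numba-compiled; all randomness flows
through seeded `numpy` generators, and a fixed seed makes every scan
byte-reproducible.

Degenerate inputs: zero-variance series, zero-diameter trajectories,
non-positive pulse widths, and series shorter than the embedding span or
the reference length are rejected with specific messages; integration
blow-up reports the failing step index.
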
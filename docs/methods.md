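# Methods

This note documents the models, parameter choices and numerical
decisions behind `lumbargait`, and what the synthetic-data tests do and
do not establish about real recordings.

## Signals and conventions

The pipeline consumes two channels of a lumbar-worn IMU: anteroposterior
(AP) linear acceleration (m/s², the sensor's z axis) and angular
velocity about the sagittal axis (deg/s, the x axis), uniformly sampled
(reference rate 128 Hz).  Time is kept in seconds internally.  Intervals
are half-open `[start, stop)` in 0-based sample indices.  All filtering
is zero-phase (forward–backward application): the deliverable is event
*timing*, and a causal filter's group delay would bias every event by a
phase lag.  Acceleration is used raw (not gravity-compensated): the 1 Hz
high-pass edge of the band-pass removes the quasi-static gravity
component, so an orientation estimate is unnecessary.

Missing samples are linearly interpolated for runs of at most 3 samples
(23 ms at 128 Hz) and rejected beyond that, because the zero-phase IIR
filters assume uniform sampling.

## Turn segmentation

Turning phases are found on the envelope of the sagittal-axis angular
velocity: band-pass (Butterworth, design order 4 per edge, 1–50 Hz) →
rectify → Savitzky–Golay (order 2, frame 1101 samples ≈ 8.6 s).  The
envelope is clipped at zero because the SG kernel's negative sidelobes
undershoot near strong bursts while the underlying quantity is
nonnegative.

Frame lengths are durations in disguise: 1101 samples at 128 Hz is
8.6 s, so at other sampling rates frames scale by `fs/128`, rounded to
the nearest odd integer.

**Threshold selection.**  The per-subject threshold is chosen by a
plateau scan: 100 candidate thresholds are spaced linearly between the
5th and 95th percentile values of the envelope; for each candidate the
number of supra-threshold runs of duration ≥ `min_turn_s` (default 1 s —
a 180° turn at walking speed takes at least that) is counted, and the
threshold is the midpoint of the widest contiguous candidate interval on
which the count is constant and positive.  The rationale: the true turn
count is stable over a broad band of thresholds between the walking
baseline and the burst peaks, whereas spurious counts (merged or
fragmented windows) survive only on narrow bands.  The scan is
percentile-based and therefore invariant to amplitude scaling.  When the
protocol fixes the number of turns (known path length and duration),
`expected_turn_count` pins the plateau to that count.  Degenerate
inputs: an all-zero envelope yields a sentinel threshold producing zero
turns.

Supra-threshold runs closer than `merge_gap_s` (default 0.5 s) are
merged, runs shorter than `min_turn_s` dropped.  Walking segments are
the complement; segments shorter than `min_walk_s` (default 2 s, below
which no full gait cycle fits) are discarded.

## Event detection

Each straight-walk segment is processed by the ROI cascade: band-pass
(1–50 Hz, order 4) → Savitzky–Golay (order 50, frame 801 ≈ 6.3 s) →
running median (order 10).  The cascade behaves as a ~1–5 Hz band
limiter that merges each step's two positive peaks into one positive
lobe and its valley into one negative lobe; its zero crossings (exact
zeros attach to the following run; boundary-touching runs are dropped as
truncated lobes) delimit alternating-polarity ROIs.  Events are
localised on the **raw** signal — argmax in positive ROIs (heel-strike,
the second and larger peak of the step pattern), argmin in negative ROIs
(toe-off) — never on the filtered signal, whose smoothing would distort
extremum positions.  Ties take the earliest extremal sample.  Leading
and trailing toe-offs are trimmed so each segment's sequence starts and
ends with a heel-strike, which anchors cycle construction.

Segments shorter than the (rate-scaled) 801-sample frame are skipped
with a log entry rather than processed with a shrunken frame; this keeps
the filter response identical across segments.

**Numerics of the order-50 Savitzky–Golay.**  Polynomial order 50 over
an 801-sample frame is far outside the regime where monomial-basis
normal equations (or even monomial-Vandermonde least squares) are
usable: the condition number is astronomically large and the resulting
convolution weights are numerically meaningless.  The smoother is
therefore built from a Legendre–Vandermonde basis on the frame, mapped
to [−1, 1], orthonormalised by QR; the centre-evaluation weights are a
row of the resulting projection matrix.  The basis is orthonormal to
~1e−15 and the filter reproduces low-degree polynomials to ~1e−8 even at
order 50.  Edges use mirror padding (band-limited near boundaries)
rather than off-centre polynomial evaluation, which at order 50 would
oscillate near the window ends and fabricate zero crossings; boundary
ROIs are discarded anyway.  At low orders the implementation agrees with
`scipy.signal.savgol_filter(mode="mirror")` to 1e−10, which the test
suite uses as an independent cross-check.

**Median filter of even order.**  "Order 10" is honoured literally: the
window covers samples `i−5 … i+4` and the median of an even window is
the mean of the two central order statistics; edges use edge-value
padding.

**Brute-force parameter tuning.**  `tune_filter_parameters` scores each
(polyorder, frame) candidate by the coefficient of variation of the
inter-heel-strike intervals the full detection produces on the segment —
steady gait has near-constant step time, so a cleaner segmentation gives
a lower CV.  Ties go to the defaults (50, 801); grids producing fewer
than 3 heel-strikes raise a tuning error.

**Side labels.**  A single lumbar sensor cannot observe laterality.
Heel-strikes alternate sides from a configurable `first_side`; each
toe-off takes the side opposite the preceding heel-strike (the foot
leaving the ground during early stance is the contralateral one).  All
reported parameters are averaged over both anchor sides, so the choice
is immaterial; the test suite verifies the summary is bit-identical
under relabelling.

## Spatiotemporal parameters

Cycles are built per segment for both anchor sides from every
five-event window HS_a, TO_b, HS_b, TO_a, HS_a; malformed windows are
skipped and logged, and cycles never span segments.  Per-cycle formulas
are in the README; ST + SW = 100 and DS = IDS + TDS are algebraic
identities and are asserted as exact invariants.

**Cadence inputs.**  Cadence is 60 · steps / walking time.  Counting
every detected heel-strike against the full summed segment duration
would bias cadence low, because segment edges are trimmed by
construction (turning phases excluded, boundary ROIs and dangling
toe-offs dropped): the denominator would include spans that cannot
contain detected events.  Each segment therefore contributes the span
between its first and last heel-strike and the steps completed in it
(heel-strikes − 1, both feet pooled).  For steady gait this makes
cadence × mean GCT = 120 exactly (two steps per cycle), which is also
asserted in the tests.

## Agreement battery

* Paired test: Shapiro–Wilk on the differences at α = 0.05 selects
  Student's paired t (normality not rejected) or Wilcoxon signed rank
  (zero differences dropped; exact null for ≤ 25 nonzero differences,
  normal approximation with continuity correction above).
* Passing–Bablok: slope = K-shifted median of all pairwise slopes
  (ties in x dropped, slopes of exactly −1 excluded, K = #{slopes < −1});
  CI by the rank-based normal approximation with
  C = z·√(n(n−1)(2n+5)/18); intercept = median(y − m·x), its CI
  evaluated at the slope-CI endpoints.  A slope CI excluding 1 flags a
  proportional systematic error; an intercept CI excluding 0 a constant
  one.
* Bland–Altman: bias = mean difference, sd with n−1 denominator, limits
  of agreement bias ± 1.96·sd, bias CI bias ± 1.96·sd/√n.  The z-factor
  (not Student t) is used throughout; `ba_from_loa` inverts the
  construction (bias = LOA midpoint, sd = LOA width / 3.92), which makes
  reported agreement tables checkable for internal consistency.
* Verdict: a proportional error ⇒ disagreement.  A constant-only error
  (PB intercept or BA bias CI excluding 0) is flagged but does not by
  itself overturn agreement — a small constant bias can be negligible
  for the use case while a proportional error distorts the measurement
  range.

Note that Passing–Bablok assumes measurement error in *both* methods;
regressing a noisy method on error-free truth biases the slope away
from 1 (a standard errors-in-variables effect).  The simulation studies
therefore give both synthetic methods comparable noise.

## Synthetic gait generator

The generator emulates the back-and-forth walk test: `n_passes` straight
passes (default 12) of `n_steps_per_pass` steps (default 16, ≈ 0.63 m
steps on a 10 m path) separated by 2 s turns; cycle time 1.16 s
(cadence ≈ 103 steps/min), stance 60%, double support 20% — values
typical of healthy adults at comfortable speed.  The default recording
is ≈ 142 s: slightly over the nominal two minutes, as the protocol
completes the final pass.

AP acceleration: per step, two positive Gaussian bumps (the first at
60% of the second's amplitude, leading it by 0.12·GCT; the second
centred exactly on the heel-strike) and one negative bump at the
toe-off; σ = 40 ms; additive white noise (default sd 0.05 m/s² against
a 2 m/s² heel-strike peak, typical of MEMS accelerometers).  Gaussian
bumps make the true extremum locations analytic, so event-timing error
is exactly measurable.  Each pass starts with the standing foot's
toe-off (a virtual heel-strike one step earlier) and ends in
double-stance standing (the trailing foot's toe-off is not emitted), so
events alternate HS/TO strictly.

For alternating gait the terminal double support is structurally
(stance − ½)·GCT, so `ds_fraction` must equal 2·stance_fraction − 1;
inconsistent settings raise a config error.  A nonzero `asymmetry`
shifts left heel-strikes by that fraction of GCT, trading IDS against
TDS at constant DS.

Angular velocity: a 12 deg/s oscillation at the stride frequency during
walking, plus 90 deg/s bursts during turns, modelled as a raised-cosine
envelope modulating a 1.4 Hz carrier — turns are executed through pivot
steps, so the gyroscope sees oscillatory content above 1 Hz, which is
what survives the pipeline's 1 Hz high-pass edge (a slow unmodulated
ramp would not).

**What the simulator does not model:** stride-time variability, soft
tissue artefact, sensor misalignment, asymmetric or pathological step
morphology, gait during turning, and drift.  Passing the recovery tests
therefore establishes correctness of the *chain* (segmentation → ROI →
extremum → parameters) under the assumed morphology, not clinical
validity on real signals; on real data the phase parameters (stance,
swing, double support) are known to be the fragile ones for lumbar
placements.

**Evaluation convention.**  Detector scoring uses ground-truth events at
least one gait cycle inside a detected walking segment.  Edge events are
excluded by design — turning phases are out of scope and each segment's
first/last partial stride is trimmed deliberately — mirroring the common
practice of dropping the first and last stride of a walking bout when
rating event detectors.  With this convention the default-configuration
pipeline matches 100% of interior events within ±3 samples (median
error ≈ 0.5 samples) and recovers GCT and cadence within 0.2%, stance
and swing within ~0.6 points and double support within ~1.2 points
across 20 seeds (the residual phase-parameter bias comes from
overlapping bump tails shifting raw-signal extrema by ~1 sample — a
genuine property of raw-extremum localisation on composite waveforms,
not of the implementation).

## Problem sizes used in the shipped analyses

The acceptance script uses 20 simulated subjects (~18k samples each) for
parameter recovery, the same runs for event-timing metrics, and 200
replicates of n = 30 subjects for the proportional-error flag study —
sizes chosen to keep the full reproduction in the seconds range while
estimating rates to a few percent.
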
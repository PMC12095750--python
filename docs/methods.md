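# Methods

This package re-implements, as tested reusable code, the bespoke
computations of a closed-loop motor-learning experiment: head-fixed mice
pull a 60 mm rotary wheel; layer-VI corticothalamic (CT) neurons in
motor cortex are imaged, photolabeled, optogenetically perturbed, and
recorded in slices. Raw recordings are not bundled; every stage is
instead exercised on a synthetic-data generator with known ground truth,
so the tests demonstrate correctness of the *computations*, not
re-derivation of the biological results.

## Task model and behavior decoding

A trial commences when three gates hold simultaneously at one sample:
the IR beam at the wheel apex is broken, the rungs register capacitive
contact, and wheel velocity exceeds a minimum gate (default 2 cm/s,
excluding sensor jitter). A 1 s refractory prevents double-triggering on
one pull. A trial is successful if velocity reaches the success
threshold within 200 ms of trial start. The success threshold was
calibrated per animal in the original task and has no published value;
it is a required configuration parameter (synthetic default 8 cm/s).

Wheel velocity is decoded from a 10-bit absolute encoder: counts are
converted to angle, unwrapped across the counter boundary, smoothed with
a centered 50 ms moving average (applied to position, before
differentiation), and differentiated to linear velocity using the wheel
radius. Per-trial metrics are the maximum velocity over the trial and
the pull distance (integral of positive velocity).

Pulls (movements regardless of trial gating) are local velocity maxima
above a minimum peak, merged within a 300 ms refractory (higher peak
kept), with onset/offset at the nearest sub-threshold crossings. Pulls
are grouped into peak-velocity bins 2–6, 6–10, 10–14 and ≥14 cm/s
(half-open intervals; exactly 14 cm/s enters the top bin so the bins are
exhaustive above 2 cm/s; slower pulls are unbinned). Velocity-matched
comparisons subsample both groups to the per-bin minimum count (seeded,
without replacement), giving equal bin histograms.

## Calcium analysis

Extracted ΔF/F traces (source extraction itself is out of scope) pass
through:

1. **Deduplication.** Source extraction can return several ROIs of one
   neuron (soma plus dendritic branches). Units are visited in order of
   decreasing trace variance (tie → lowest ID) and kept only if their
   Pearson correlation with every kept unit is ≤ 0.8, so the
   highest-variance member — the putative trunk — survives each
   correlated group. Constant traces are dropped with a warning.
2. **Z-scoring.** Whole-session per-unit standardization for
   session-level analyses; for peri-event analyses, standardization to
   the pre-movement window 2–1.5 s before the event.
3. **Alignment.** Unit × event × time snippets around pull maxima;
   events whose window leaves the recording are dropped and counted.
4. **Classification.** On each unit's event-averaged trace over
   [−2, +2] s around pull max, 40 trapezoidal 100 ms bin integrals are
   computed (the trace is linearly interpolated to a 1 ms grid so bin
   edges falling between 16 Hz samples are handled exactly) and z-scored
   to the mean and sample SD (ddof = 1; five values are a small sample
   and the biased estimator inflates false positives) of the first five
   bins. The decision window is the 600 ms around pull max: three bins
   before and three after. **Default rule (strict):** a unit is *up*
   (*down*) if at least two bins in each 300 ms half exceed z = 2
   (fall below −2). A relaxed reading — at least two qualifying bins
   anywhere in the combined six — is available via a flag, but is not
   the default because it is unusable as a detector: on unmodulated
   (pure-noise) units it produces ~22% false positives, and since the
   bin z-scoring removes any amplitude scale this rate cannot be reduced
   by any signal-to-noise level (measured on 2000 noise units; the
   strict rule yields ~2%, i.e. >95% specificity). If both up and down
   criteria are met, the larger qualifying-bin count wins (tie → larger
   |summed z|). Zero baseline-bin SD → non-modulated, flagged
   degenerate. Class percentages are reported over classified units.
5. **Cross-correlation.** Activity and velocity (velocity linearly
   interpolated onto the imaging clock) are standardized over their full
   length; lagged product sums are divided by the overlap count, so the
   lag-0 autocorrelation is exactly 1. Negative lag means the activity
   change precedes velocity. The null control circularly shifts the
   activity trace by uniform offsets ≥ 30 s (preserving autocorrelation,
   destroying pairing) and reports the mean and a percentile envelope
   over shuffles. Per-population summaries histogram the lag of each
   unit's correlogram minimum in 50 ms half-open bins (a lag exactly on
   an edge joins the bin opening there) and summarize minima by mean and
   quartiles. The modulation range is per-unit max − min of the aligned
   average within a window.

A classification caveat documented rather than resolved: the published
per-class counts for this experiment (740 + 168 + 168) sum to 1076 while
the stated session-level unit count is 1078; percentages here are always
computed from classified totals.

## Photoconversion model and labeling simulator

Light dose through the cranial window follows a 1-D Beer–Lambert model,
deliberately matching the original calculation (no NA-dependent beam
spread): fiber-tip irradiance E₀ = P / (π (d/2)²) with P = 60 mW and
d = 960 µm giving 82 893 W/m² = 82.89 mW/mm², attenuated as
E(z) = E₀ e^(−μₜ z) with μₜ = μₐ + μₛ. Defaults μₐ = 0.2 mm⁻¹ and
μₛ = 5 mm⁻¹ (the value used in the original worked depth table, although
the accompanying text estimates scattering nearer 2 mm⁻¹; both are
configurable) give μₜ = 5.2 mm⁻¹ and reproduce the printed depth table
to ±0.01 mW/mm².

Schedules: unbiased delivery is 5 s on / 5 s off for 12 min (72 pulses,
360 s total on-time); closed-loop delivery is a 500 ms pulse at each
trial start (trials-ON) or only outside trial intervals (trials-OFF),
with at least 2 s between pulses (violating trial starts are skipped and
counted).

The labeling simulator has no quantitative photoconversion kinetics to
draw on, so conversion is modeled as coincidence: per-unit score =
∫ rectified ΔF/F × light dt, additive over disjoint light intervals; a
unit is labeled when its score reaches a threshold. Comparisons between
trials-ON and trials-OFF schedules are made at matched total on-time
(trailing pulses of the longer schedule dropped) and, absent an absolute
calibration, at the pooled-median score threshold. For
movement-suppressed populations this reproduces the qualitative
direction of the closed-loop labeling experiment: more units labeled
outside trials than during them.

## Optogenetic schedules and stratified metrics

Closed-loop: a seeded random subset of trials — exact count
round(fraction × n), sampled without replacement per session (the
original description, "one third of trials", does not state the
mechanism; exact enforcement is the default) — receives a train at trial
start + delay (0 ms for the trial-start variant, 110 ms for the
velocity-max variant). Trains are 400 ms at 20 Hz with 10 ms pulses
(8 pulses). Open-loop: non-overlapping 1.2 s trains (24 pulses at
20 Hz) at seeded random onsets covering one tenth of the session within
one train.

A trial is light-on if any train overlaps its interval. Two success
percentages are computed: successful-with-light-on = successful light-on
trials / all successful trials; per-condition percent success =
successful trials in a condition / trials in that condition. Kinematic
means (max velocity, pull distance, limb displacement) aggregate
unweighted along trial → session → animal when grouping columns are
present. Limb displacement uses frame-to-frame Euclidean distances of
the tracked wrist keypoint: per-trial maximum for wheel pulls, summed
path length for locomotion bouts; intervals with missing frames are
excluded.

## Slice electrophysiology metrics

On the trial-averaged sweep, baseline statistics come from the 10 ms
immediately pre-stimulus. Onset is the first post-stimulus time at which
|current| exceeds 3 × baseline SD for ≥ 1 ms sustained (the published
latencies come with no stated detection rule; a sustained
threshold-crossing on the average is the standard conservative choice);
the peak is the signed extremum within the 100 ms stimulus window
(inward/negative at −70 mV, outward/positive at 0 mV); steady state is
the mean over the final 20% of the stimulus window; responses never
crossing threshold are reported absent. The I/E ratio is |I|/|E| and is
sign-free. Grand averages optionally normalize each cell by its
steady-state magnitude (near-zero steady states excluded with a
warning) and resample to a common time base before mean ± SEM.

## Synthetic-data generator

The generator defines the study conditions for all tests:

- **Session** (default 300 s): behavior sampled at 2000 Hz, imaging at
  16 Hz, 60 mm wheel with a 1024-count absolute encoder. Pulls are
  raised-cosine velocity bumps of 0.5 s width (smooth, integrable,
  analytic peak) at non-overlapping seeded onsets; peak velocities are
  lognormal(μ = 2, σ = 0.3) in cm/s (mean ≈ 7.7 cm/s, matching a
  mid-training animal), configurable by family. Beam and capacitance are
  active for each pull's duration; the encoder channel is the quantized
  integrated angle; velocity noise is additive Gaussian (0.05 cm/s).
  Ground-truth trial starts apply the same velocity-gate predicate the
  detector uses, so noiseless round-trips are exact.
- **Population** (default 100 units; proportions 69/16/15
  down/up/no-mod, the published classification): each pull contributes a
  transient — amplitude = gain × peak velocity, gain default
  0.05 ΔF/F per cm/s with lognormal(σ = 0.2) per-unit heterogeneity and
  lognormal(σ = 0.6) per-unit-per-pull trial-to-trial jitter — placed at
  pull max + lag (default −150 ms: suppression slightly precedes the
  velocity peak) and convolved with a single-exponential calcium kernel
  (τ = 0.7 s; the indicator's kernel is not published, a single
  exponential is the standard minimal choice). Down units subtract the
  transient from a tonic baseline (0.2 ΔF/F), up units add it, no-mod
  units are baseline plus i.i.d. Gaussian noise (0.05 ΔF/F). The
  trial-to-trial jitter matters beyond realism: without it all down
  units share identical drive and correlate above the 0.8 deduplication
  threshold with *each other*, which real populations do not.
- **Duplicate branches** are attenuated noisy copies of a parent:
  branch = 0.9 × (ρ·parent + √(1−ρ²)·σ·ε) about the parent mean, hitting
  the target correlation (default 0.9) while leaving the parent the
  highest-variance member of its group — the configuration the
  deduplication rule assumes. A branch built as parent + independent
  noise would necessarily *exceed* the parent's variance.
- **Keypoints**: wrist coordinates whose per-frame displacement is
  coupling × velocity / frame-rate along a fixed direction plus
  isotropic jitter — a linearized stand-in for pose-estimation output.
- **Ephys sweeps**: baseline noise, half-cosine rise (2 ms) to the
  target peak at onset latency, exponential relaxation (τ = 10 ms) to
  the steady state, and return to baseline after the 100 ms stimulus.
  Default latency scales follow the published ranges (~6 ms excitatory,
  ~13 ms inhibitory in trained animals).

What the generator does **not** emulate: sensor crosstalk or slow drift,
indicator photobleaching, correlated (network) noise, pull-shape
variability beyond amplitude, limb biomechanics beyond linear coupling,
and synaptic kinetics beyond a fixed rise/decay. Passing tests therefore
certify the pipeline's arithmetic, conventions and recovery behavior
under these idealized conditions — not performance on raw recordings.

## Problem sizes and numerical choices

Test and analysis runs use 300 s sessions with 60 pulls, populations of
50–2000 units, 100-seed batteries for the labeling and ephys recovery
checks, and 100 circular shuffles for null bands; these sizes give
stable estimates (binomial/CLT envelopes are asserted where relevant)
while keeping any single run in the seconds range. Times are seconds
from session start, intervals half-open [onset, offset); event tables
are tab-separated with 6-decimal floats (making repeated runs
byte-identical); all randomness flows from named integer seeds through
`numpy.random.default_rng`. The analysis drivers under `analysis/` are
thin narratives over `src/ctmotor`; the library functions and scripts
are the interface (no console entry point is installed).
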
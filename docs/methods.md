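# Methods

This note documents the models, estimators, numerical choices, and known
limitations of `reservoir-events`, in the spirit of a model-description
appendix.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Dynamics

The reservoir is a discrete-time leaky echo state network,

    x(t+1) = (1 − α) x(t) + α tanh(W x(t) + W_in u(t)),

with `W` (N×N) and `W_in` (N×K) drawn i.i.d. uniform on [−0.5, 0.5] from
a seeded generator.  Defaults N = 1000, K = 100, α = 0.05 — a leak rate
small enough that the state is a long-memory summary of the embedding
stream, chosen for the high volatility of word-embedding input.  Because
each update is a convex mixture of the previous state and a tanh output,
states started in (−1, 1)^N remain there.

**Spectral-radius normalization.**  `init_reservoir` rescales `W` so its
spectral radius is 1.0, the standard echo-state-network convention (and
the default of common reservoir libraries).  The raw uniform matrix at
N = 1000 has spectral radius ≈ 9; in that regime the tanh units saturate
(|x| → 1), trajectories ride attractor-like plateaus, and the
intact-scrambled difference signal grows for hundreds of steps without
reaching a plateau, which breaks the half-life estimators below.  With
radius 1 the network has the fading-memory property: a bounded
perturbation decays, the difference signal saturates within a few steps
of an input divergence, and the construction-time spectrum is broad and
reproducible.  `spectral_radius=None` disables the rescaling for anyone
wanting the raw regime; the runner logs a warning when trajectories
approach saturation.

The linear integrator is `LI(n) = (1 − α) LI(n−1) + g·u(n)` applied
elementwise.  The default input gain is g = 1 + α (`as_printed`); the
conventional leaky average g = α is available as `convex`.  The gain only
scales the state, so every qualitative result (asymmetry, time
constants) is gain-invariant; the constant-input fixed point under the
default is (1 + α)/α = 21.0 at α = 0.05.  The gain is kept configurable
rather than silently normalized.

**Step-response probe.**  Zero input for 500 steps, a constant vector for
400, zero again for 600 (lengths configurable).  Per-unit
time-to-stabilize after a transition is the first step at which the
distance to the unit's asymptote — estimated as its mean over the last
quarter of the window — falls to half the distance at the transition.
Units starting within 1e−9 of the asymptote are flagged undefined
(below numeric noise for tanh dynamics); units that never halve are
censored at the window length.  For the integrator this reduces to the
closed form ⌈log ½ / log(1 − α)⌉ = 14 steps at α = 0.05, identical
across units.

## Event segmentation model

A left-to-right Gaussian HMM with k events that each occur exactly once,
in order, with no skips.  The chain starts in event 1 and the likelihood
is conditioned on ending in event k; the per-step advance probability is
(k − 1)/(T − 1), giving exactly k − 1 expected advances over T − 1
transitions (geometric dwell with mean ≈ T/k).

Observations are spatial patterns z-scored across units at each
timepoint, modeled as isotropic unit-variance Gaussians around per-event
mean patterns.  Per-timepoint z-scoring makes the model scale- and
offset-invariant per pattern — note the consequence that a spatially
uniform activity shift is invisible to the model; only pattern *shape*
changes drive boundaries.  Fitting alternates forward–backward posterior
estimation (in log space) with re-estimation of event means as
γ-weighted averages; with the variance fixed, this is exact EM, so the
conditional log-likelihood is nondecreasing — asserted on every fit, with
a 1e−6 relative slack for floating-point.  Convergence: improvement
< 1e−4 or 200 iterations; initialization is the deterministic even split
of the timeline into k contiguous chunks.  Constant (zero-spatial-
variance) timepoints are rejected with a clear message.

Hard boundaries are the first steps of each new event under the
per-timepoint argmax of γ (ties toward the earlier event, running
maximum enforcing monotonicity).  Scoring a trajectory under a fitted
model reuses the identical observation model and chain, so scoring the
training trajectory reproduces the stored log-likelihood exactly.

**Detection lag.**  On leaky-integrated trajectories, detected
boundaries systematically trail the input transitions by roughly the
state half-life (≈ 14 steps at α = 0.05 for the integrator; ~7–8 steps
for reservoir states), because the state pattern crosses over to the new
section's pattern only after the old contribution has decayed.  Boundary
tests on model trajectories should anticipate this lag; planted-boundary
recovery is therefore validated on raw streams, where recovery is exact.

## Boundary statistics

`match_count` counts reference boundaries that have a model boundary
within ±tol steps (default 3), under greedy one-to-one pairing in
increasing order, so one model boundary cannot absorb several reference
boundaries.  The counting direction is reported both ways
(`n_match`, `n_match_model`); they coincide except in dense tie
configurations.

The permutation null holds the multiset of event lengths (including the
first and last segments) fixed and shuffles their order, 1000 times by
default.  The observed count is converted to z = (obs − mean)/sd against
the null sample (sd with ddof = 1) and to a one-sided upper-tail normal
p — the hypothesis is an excess of matching.  If the null has zero
spread (e.g. all event lengths equal, so every shuffle reproduces the
same boundaries), the test is uninformative: p = 1 and z is flagged
undefined rather than silently 0.  Type-I calibration of this procedure
is checked by simulation in the acceptance suite.

## Context construction and forgetting

A paired run drives two copies of one model instance (same weights, same
initial state, default x0 = 0) with intact ABCD and scrambled ACBD
streams.  Strict mode requires |B| = |C| so the difference trajectory is
step-aligned; a permissive mode truncates the longer middle.  One master
seed spawns independent sub-generators per section, so sections are
reusable across conditions.  Default synthetic study conditions:
sections of 100/200/200/100 i.i.d. standard-normal steps in 100
dimensions.

The difference trajectory (intact − scrambled) is exactly zero before
the same→different transition (bit-identical arithmetic on a shared
prefix).  Per-unit **construction (alignment) time** is the first step
after the different→same transition at which |difference| falls to half
its value at the transition; window defaults to everything after the
transition.  Initial magnitudes below 1e−9 are undefined; non-halving
units are censored.  Per-unit **forgetting time** — no standard
estimator exists, so the package defines one symmetric to construction:
the first step after the same→different transition at which |difference|
rises to half its plateau, where the plateau is the unit's mean
|difference| over the last quarter of the forgetting window (default:
the scrambled period).  Near-zero plateaus are flagged undefined.

Inter-run pattern correlation (IRPC) is the Pearson correlation between
spatial patterns at step i of one run and step j of the other, after
subtracting each unit's temporal mean within its run — the centering
prevents a large shared baseline from saturating all correlations.
Zero-variance patterns give NaN entries, never a silent 0.

**Virtual areas** are contiguous bands of units ranked by construction
time (ascending, 0-based, ties broken by unit index, undefined last):
`fast_slow_100` takes ranks 100–199 and 800–899 — one band in from each
extreme, avoiding the most outlying units; `five_by_200` partitions all
1000 ranks into five bands.  Rank positions, not original unit ids, are
what the schemes name.  Undefined/censored units are excluded from area
means and from the construct–forget Spearman correlation (computed over
units with both times defined; at least 10 required).

## Segmentation-effect experiment

For each instance: a fresh reservoir, a two-timescale ABCD/ACBD pair
(sections of 160 steps, matching the ~650-step scale of a real
transcript), fast/slow areas from the paired run's alignment times, and
event-HMM fits of each area's intact-condition trajectory at k_small = 4
and k_large = 16.  The effect is the log-likelihood contrast defined in
the README; significance across instances is a one-sided one-sample t
test of the per-instance effects against zero (a paired t test on the
two k-assignments).  Zero-variance effect vectors resolve by sign.
Instance seeds are consecutive from the experiment seed.  The fitted
(training) likelihood is used on both sides of the contrast — no held-out
scoring — and the intact condition is the canonical trajectory.

## Synthetic data: what it emulates and what it does not

- `gen_topic_stream` emulates a narrative concatenated from distinct
  sources: per-topic mean patterns drawn N(0, sep²/D) per coordinate
  (mean norm ≈ `topic_sep`, dimension-free) plus isotropic noise.
  Section lengths may differ per topic, as in real text — and must, for
  the length-shuffle permutation test to have power.
- `gen_gaussian_stream` is the fully unstructured control used for the
  asymmetry experiment: the asymmetry is a property of leaky
  integration, not of input correlations, and the Gaussian stream
  demonstrates exactly that.
- `gen_two_timescale_stream` superposes slow (40-step) and fast (8-step)
  block-mean structure with amplitudes 3.0/1.5 and per-dimension noise
  0.5 — nested coarse/fine event structure as a granularity-preference
  probe.
- None of the generators model lexical semantics: tokens are labels, and
  embedding statistics of real narratives (heavy-tailed norms, semantic
  autocorrelation, topic recurrence) are not reproduced.  Passing tests
  on these streams validates the machinery and the integrator-level
  phenomena; it does not certify behavior on real narrative embeddings.

## Known limitations

- **The segmentation effect is weak on synthetic input.**  Units ranked
  by alignment time do not measurably differ in driven-activity
  autocorrelation under Gaussian-based streams, so the fast/slow areas'
  granularity preference — readily expressed as a log-likelihood
  contrast — fluctuates in sign across instances, and ten instances are
  generally not enough for significance at 0.05.  The corresponding
  acceptance check is asserted at its stated threshold and currently
  fails; the effect reported on real narrative input in the literature
  appears to require the temporal statistics of real text.  The
  `examples/04_virtual_areas.py` script shows a single-instance contrast.
- Detected boundaries on leaky trajectories lag input transitions (see
  above); analyses comparing model boundaries to input-time ground truth
  at tight tolerances must account for this.
- The HMM's fixed unit observation variance makes log-likelihoods
  comparable across k but ties the noise scale to the z-scoring; data
  with strongly non-isotropic pattern noise would need a variance
  parameter.
- No temporal smoothing is applied before segmentation, and no automatic
  selection of k is provided beyond explicit grids.
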
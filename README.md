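# reservoir-events

Narrative event segmentation in reservoir dynamics: drive a leaky
echo-state network (and a linear-integrator baseline) with word-embedding
streams, segment the resulting state trajectories with an event HMM, and
analyze how the network constructs and forgets narrative context.

## Who this is for

Computational neuroscientists and cognitive modelers studying how
cortical-like recurrent dynamics give rise to the event structure seen in
human fMRI during narrative listening: hierarchies of processing
timescales, the asymmetry between abrupt context forgetting and gradual
context construction, and the link between a region's timescale and its
preferred event granularity.  Everything runs on synthetic embedding
streams, so no imaging data or pretrained embeddings are required; real
text plus a word2vec-format table plugs into the same pipeline.

## The models

**Reservoir.** A discrete-time echo state network of `N` tanh units with
leak rate α and fixed random weights:

```
x(t+1) = (1 − α) x(t) + α tanh(W x(t) + W_in u(t))
```

`W` (N×N) and `W_in` (N×K) are i.i.d. uniform on [−0.5, 0.5]; `W` is
rescaled to spectral radius 1 (echo-state convention).  `u(t)` is the
embedding of the t-th word.  No readout is trained — the object of study
is the state trajectory itself.  Defaults: N = 1000, K = 100, α = 0.05.

**Linear integrator baseline.** `LI(n) = (1 − α) LI(n−1) + (1 + α) u(n)`,
elementwise; it shares the leaky memory but has no recurrent mixing, so
all of its units share one time constant.

**Event HMM.** A left-to-right Gaussian hidden Markov model: k events
occur once each, in order; observations are per-timepoint spatial
patterns z-scored across units, modeled as unit-variance Gaussians around
per-event mean patterns.  Fitting is EM with forward–backward posteriors;
the per-timepoint event posterior γ (T×k) yields hard boundaries and the
co-segmentation probability `γ_A γ_Bᵀ` between two recordings.

**Boundary statistics.** Two segmentations are compared by counting
reference boundaries with a model boundary within ±3 steps (greedy
one-to-one).  Significance comes from a null that shuffles the order of
the model's event lengths (1000 permutations → z → one-sided p).

**Context experiment.** Two identical model copies hear intact (ABCD) and
scrambled (ACBD) streams.  Their state difference is zero during A, jumps
abruptly when inputs diverge (forgetting), and decays gradually once they
re-align (construction).  Per-unit half-life times of this difference
define construction/forgetting time constants; sorting units by
construction time and cutting rank bands yields "virtual areas" whose
event-granularity preference is scored by the log-likelihood contrast

```
effect(k_i, k_j) = [ll(k_i, slow) + ll(k_j, fast)] − [ll(k_j, slow) + ll(k_i, fast)],  k_i < k_j
```

## Worked example

`python examples/03_construction_forgetting.py` runs the paired
intact/scrambled experiment at full scale (N = 1000, α = 0.05, Gaussian
sections of 100/200/200/100 steps) and prints:

```
max |difference| before divergence : 0.0
median forgetting time             : 2 steps
median construction time           : 15 steps
construction-time IQR across units : 7 steps
construct vs forget Spearman       : rho = 0.069, p = 0.03
```

While both copies hear the same section the trajectories are
bit-identical (difference exactly 0).  After the inputs diverge the
difference saturates within ~2 steps (forgetting is input-driven); after
they re-align it takes a median of ~15 steps to halve (construction is
memory-driven), with a broad spread across units (IQR 7) that is
essentially unrelated to forgetting speed — the asymmetry and
time-constant hierarchy this package exists to reproduce.  The other
examples cover topic-boundary segmentation, step-response time
constants, virtual areas, and the text-to-embedding pipeline; the
`reservoir-events` CLI drives the same pipelines from TOML configs.

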
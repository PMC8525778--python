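"""Synthetic word-embedding streams with known ground truth.

The analyses in this package operate on sequences of per-word embedding
vectors.  Real narratives require a pretrained embedding table (see
:mod:`reservoir_events.embeddings`); the generators here emulate the
statistical structure those inputs provide — topic blocks with planted
boundaries, i.i.d. Gaussian streams, and intact/scrambled (ABCD vs ACBD)
section pairs — so every downstream stage can be exercised without any
external download.
"""

from __future__ import annotations

import json
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EmbeddingSequence",
    "StreamPair",
    "gen_gaussian_stream",
    "gen_topic_stream",
    "gen_two_timescale_stream",
    "make_intact_scrambled",
    "save_stream",
    "load_stream",
]


@dataclass
class EmbeddingSequence:
    """A sequence of per-step input vectors with optional ground truth.

    Parameters
    ----------
    tokens:
        One label per time step.  For synthetic streams these are
        generated labels, not words.
    matrix:
        ``(T, D)`` array; row ``t`` is the input vector ``u(t)``.
    true_boundaries:
        Strictly increasing step indices in ``(0, T)`` at which a new
        ground-truth section begins.  Empty when no ground truth exists.
    meta:
        Free-form provenance (seed, generator name, parameters).
    """

    tokens: list[str]
    matrix: np.ndarray
    true_boundaries: list[int] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError(f"matrix must be 2-D, got shape {self.matrix.shape}")
        if len(self.tokens) != self.matrix.shape[0]:
            raise ValueError(
                f"{len(self.tokens)} tokens but {self.matrix.shape[0]} matrix rows"
            )
        if self.matrix.shape[1] < 1:
            raise ValueError("embedding dimension must be >= 1")
        b = [int(x) for x in self.true_boundaries]
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("true_boundaries must be strictly increasing")
        if b and (b[0] <= 0 or b[-1] >= self.T):
            raise ValueError("true_boundaries must lie strictly inside (0, T)")
        self.true_boundaries = b

    @property
    def T(self) -> int:
        return self.matrix.shape[0]

    @property
    def D(self) -> int:
        return self.matrix.shape[1]


@dataclass
class StreamPair:
    """Intact (ABCD) and scrambled (ACBD) streams from shared sections.

    ``t_forget`` is the same->different transition (first step of the
    scrambled middle), ``t_construct`` the different->same transition
    (first step of the shared final section).
    """

    intact: EmbeddingSequence
    scrambled: EmbeddingSequence
    t_forget: int
    t_construct: int


def gen_gaussian_stream(T: int, D: int, seed: int) -> EmbeddingSequence:
    """i.i.d. standard-normal stream of ``T`` steps in ``D`` dimensions."""
    if T < 0:
        raise ValueError("T must be >= 0")
    if D < 1:
        raise ValueError("D must be >= 1")
    rng = np.random.default_rng(seed)
    mat = rng.standard_normal((T, D))
    tokens = [f"g{t}" for t in range(T)]
    meta = {"generator": "gaussian", "seed": seed, "T": T, "D": D}
    return EmbeddingSequence(tokens, mat, [], meta)


def gen_topic_stream(
    n_topics: int,
    tokens_per_topic: int | Sequence[int],
    D: int,
    topic_sep: float = 10.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> EmbeddingSequence:
    """Blocked stream: each topic has a fixed mean vector plus noise.

    Topic means are drawn i.i.d. ``N(0, topic_sep^2 / D)`` per coordinate so
    the expected mean norm scales with ``topic_sep`` independently of ``D``;
    each step adds isotropic ``N(0, noise_sd^2)`` noise.  Ground-truth
    boundaries are the first steps of topics ``2..n_topics``.
    ``tokens_per_topic`` may be a single count or one count per topic
    (real narrative sections rarely have equal length).
    """
    if n_topics < 1:
        raise ValueError("n_topics must be >= 1")
    if isinstance(tokens_per_topic, int):
        lengths = [tokens_per_topic] * n_topics
    else:
        lengths = list(tokens_per_topic)
        if len(lengths) != n_topics:
            raise ValueError(
                f"{len(lengths)} section lengths for {n_topics} topics"
            )
    if min(lengths) < 1:
        raise ValueError("tokens_per_topic must be >= 1")
    if D < 1:
        raise ValueError("D must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    means = rng.standard_normal((n_topics, D)) * (topic_sep / np.sqrt(D))
    rows = np.repeat(means, lengths, axis=0)
    rows = rows + rng.standard_normal(rows.shape) * noise_sd
    tokens = [
        f"topic{i}_w{j}" for i, n in enumerate(lengths) for j in range(n)
    ]
    boundaries = list(np.cumsum(lengths)[:-1].astype(int))
    meta = {
        "generator": "topic",
        "seed": seed,
        "n_topics": n_topics,
        "tokens_per_topic": tokens_per_topic,
        "topic_sep": topic_sep,
        "noise_sd": noise_sd,
    }
    return EmbeddingSequence(tokens, rows, boundaries, meta)


def gen_two_timescale_stream(
    T: int,
    D: int,
    slow_period: int = 40,
    fast_period: int = 8,
    slow_amp: float = 3.0,
    fast_amp: float = 1.5,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> EmbeddingSequence:
    """Stream with nested slow and fast topic structure.

    A slow mean vector changes every ``slow_period`` steps and a fast mean
    every ``fast_period`` steps; both are superposed with i.i.d. noise.
    Serves as a positive control for analyses that contrast coarse and
    fine event granularity.  Ground-truth boundaries are the slow ones.
    """
    if T < 0 or D < 1:
        raise ValueError("need T >= 0 and D >= 1")
    if slow_period < 1 or fast_period < 1:
        raise ValueError("periods must be >= 1")
    rng = np.random.default_rng(seed)
    n_slow = -(-T // slow_period) if T else 0
    n_fast = -(-T // fast_period) if T else 0
    slow_means = rng.standard_normal((max(n_slow, 1), D)) * (slow_amp / np.sqrt(D))
    fast_means = rng.standard_normal((max(n_fast, 1), D)) * (fast_amp / np.sqrt(D))
    t = np.arange(T)
    mat = (
        slow_means[t // slow_period]
        + fast_means[t // fast_period]
        + rng.standard_normal((T, D)) * noise_sd
    )
    boundaries = [b for b in range(slow_period, T, slow_period)]
    meta = {
        "generator": "two_timescale",
        "seed": seed,
        "slow_period": slow_period,
        "fast_period": fast_period,
        "slow_amp": slow_amp,
        "fast_amp": fast_amp,
        "noise_sd": noise_sd,
    }
    tokens = [f"tt{t_}" for t_ in range(T)]
    return EmbeddingSequence(tokens, mat, boundaries, meta)


def _concat(segs: list[EmbeddingSequence], meta: dict) -> EmbeddingSequence:
    tokens = [tok for s in segs for tok in s.tokens]
    mat = (
        np.concatenate([s.matrix for s in segs], axis=0)
        if segs
        else np.empty((0, 1))
    )
    return EmbeddingSequence(tokens, mat, [], meta)


def make_intact_scrambled(
    a: EmbeddingSequence,
    b: EmbeddingSequence,
    c: EmbeddingSequence,
    d: EmbeddingSequence,
    strict: bool = True,
) -> StreamPair:
    """Build intact ABCD and scrambled ACBD streams from four sections.

    The two streams share section A, then diverge (B vs C), then share D
    again.  The same->different index is ``|A|``; the different->same index
    is ``|A| + |B| + |C|``.  Step-aligned differencing of downstream
    trajectories requires ``|B| == |C|``; in strict mode unequal middles
    are rejected, otherwise the longer middle is truncated to match.
    """
    dims = {s.D for s in (a, b, c, d)}
    if len(dims) != 1:
        raise ValueError(f"sections must share dimension, got {sorted(dims)}")
    if b.T != c.T:
        if strict:
            raise ValueError(
                f"|B| = {b.T} != |C| = {c.T}; required for aligned comparison "
                "(pass strict=False to truncate)"
            )
        n = min(b.T, c.T)
        b = EmbeddingSequence(b.tokens[:n], b.matrix[:n], [], dict(b.meta))
        c = EmbeddingSequence(c.tokens[:n], c.matrix[:n], [], dict(c.meta))
    t_forget = a.T
    t_construct = a.T + b.T + c.T
    meta = {"generator": "intact_scrambled", "lengths": [a.T, b.T, c.T, d.T]}
    intact = _concat([a, b, c, d], {**meta, "order": "ABCD"})
    scrambled = _concat([a, c, b, d], {**meta, "order": "ACBD"})
    return StreamPair(intact, scrambled, t_forget, t_construct)


def gaussian_abcd_pair(
    len_a: int,
    len_bc: int,
    len_d: int,
    D: int,
    seed: int,
) -> StreamPair:
    """Gaussian ABCD/ACBD pair; one master seed spawns per-section streams."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    a = gen_gaussian_stream(len_a, D, seeds[0])
    b = gen_gaussian_stream(len_bc, D, seeds[1])
    c = gen_gaussian_stream(len_bc, D, seeds[2])
    d = gen_gaussian_stream(len_d, D, seeds[3])
    return make_intact_scrambled(a, b, c, d)


def save_stream(seq: EmbeddingSequence, prefix: str | Path) -> None:
    """Write a stream as plain-text tokens + matrix with a JSON sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    prefix.with_suffix(".tokens.txt").write_text(
        "\n".join(seq.tokens) + ("\n" if seq.tokens else "")
    )
    np.savetxt(prefix.with_suffix(".matrix.txt"), seq.matrix)
    sidecar = {"true_boundaries": seq.true_boundaries, "meta": seq.meta}
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_stream(prefix: str | Path) -> EmbeddingSequence:
    prefix = Path(prefix)
    tokens = prefix.with_suffix(".tokens.txt").read_text().splitlines()
    mat = np.loadtxt(prefix.with_suffix(".matrix.txt"), ndmin=2)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    return EmbeddingSequence(
        tokens, mat, sidecar.get("true_boundaries", []), sidecar.get("meta", {})
    )
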
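"""Text-to-embedding-stream input pipeline.

Turns a UTF-8 narrative plus a pretrained word-embedding table (word2vec
text format: a "V D" header line, then one token and D numbers per line)
into an :class:`~reservoir_events.synthetic.EmbeddingSequence`.  Stop
words carry little semantic content and are removed before lookup; each
retained in-vocabulary token becomes one model time step.

A fixed English stop-word list ships with the package so tokenization is
deterministic across environments.  Lookup lowercases first and falls
back to the original casing on a miss.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .synthetic import EmbeddingSequence

__all__ = [
    "STOPWORDS",
    "EmbeddingTable",
    "read_word_vectors",
    "tokenize_and_filter",
    "lookup_sequence",
    "text_to_sequence",
]

logger = logging.getLogger(__name__)

#: Standard English stop words (articles, prepositions, pronouns,
#: auxiliaries, common adverbs); fixed here for reproducibility.
STOPWORDS: frozenset[str] = frozenset("""
a about above after again against all am an and any are aren't as at be
because been before being below between both but by can't cannot could
couldn't did didn't do does doesn't doing don't down during each few for
from further had hadn't has hasn't have haven't having he he'd he'll he's
her here here's hers herself him himself his how how's i i'd i'll i'm
i've if in into is isn't it it's its itself let's me more most mustn't my
myself no nor not of off on once only or other ought our ours ourselves
out over own same shan't she she'd she'll she's should shouldn't so some
such than that that's the their theirs them themselves then there there's
these they they'd they'll they're they've this those through to too under
until up very was wasn't we we'd we'll we're we've were weren't what
what's when when's where where's which while who who's whom why why's
with won't would wouldn't you you'd you'll you're you've your yours
yourself yourselves
""".split())

_TOKEN_RE = re.compile(r"[\w']+")


@dataclass
class EmbeddingTable:
    """Token -> D-vector lookup with a single shared dimension."""

    vocabulary: dict[str, np.ndarray]
    D: int

    def __len__(self) -> int:
        return len(self.vocabulary)

    def get(self, token: str) -> np.ndarray | None:
        """Lowercased lookup with fallback to the original casing."""
        v = self.vocabulary.get(token.lower())
        if v is None:
            v = self.vocabulary.get(token)
        return v


def read_word_vectors(path: str | Path) -> EmbeddingTable:
    """Read a word2vec text-format embedding table.

    Duplicate tokens follow a last-wins policy (logged).  Malformed lines
    and dimension mismatches raise ``ValueError`` naming the line number.
    """
    path = Path(path)
    vocab: dict[str, np.ndarray] = {}
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}:1: expected header 'V D', got {header!r}")
        try:
            n_tokens, dim = int(header[0]), int(header[1])
        except ValueError:
            raise ValueError(f"{path}:1: non-integer header {header!r}") from None
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: malformed line")
            token, values = parts[0], parts[1:]
            if values and values[-1] == "":  # trailing space, common in exports
                values = values[:-1]
            if len(values) != dim:
                raise ValueError(
                    f"{path}:{lineno}: {len(values)} values, expected {dim}"
                )
            try:
                vec = np.asarray([float(v) for v in values])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric value") from None
            if token in vocab:
                logger.warning("duplicate token %r at line %d; keeping last",
                               token, lineno)
            vocab[token] = vec
    if len(vocab) != n_tokens:
        logger.warning("header declared %d tokens, file had %d unique",
                       n_tokens, len(vocab))
    return EmbeddingTable(vocabulary=vocab, D=dim)


def tokenize_and_filter(text: str, stopwords: frozenset[str] | set[str] = STOPWORDS) -> list[str]:
    """Lowercase, split on whitespace/punctuation, drop stop words.

    Order is preserved; an empty text yields an empty list.  Pass an
    empty set to retain stop words.
    """
    return [t for t in _TOKEN_RE.findall(text.lower()) if t not in stopwords]


def lookup_sequence(
    tokens: list[str],
    table: EmbeddingTable,
    oov_policy: str = "skip",
) -> EmbeddingSequence:
    """Stack embedding vectors for the tokens, one matrix row per hit.

    Out-of-vocabulary tokens are dropped and logged under the ``skip``
    policy (their identities are kept in ``meta['oov']``); under
    ``error`` the first miss aborts.
    """
    if oov_policy not in ("skip", "error"):
        raise ValueError(f"unknown oov_policy {oov_policy!r}")
    if not table.vocabulary:
        raise ValueError("embedding table is empty")
    kept, rows, oov = [], [], []
    for tok in tokens:
        vec = table.get(tok)
        if vec is None:
            if oov_policy == "error":
                raise KeyError(f"token {tok!r} not in embedding table")
            oov.append(tok)
            continue
        kept.append(tok)
        rows.append(vec)
    if oov:
        logger.warning("dropped %d out-of-vocabulary tokens (e.g. %r)",
                       len(oov), oov[:5])
    mat = np.stack(rows) if rows else np.empty((0, table.D))
    return EmbeddingSequence(kept, mat, [], {"source": "lookup", "oov": oov})


def text_to_sequence(
    text: str,
    table: EmbeddingTable,
    stopwords: frozenset[str] | set[str] = STOPWORDS,
    oov_policy: str = "skip",
) -> EmbeddingSequence:
    """Tokenize, filter, and embed a narrative in one call."""
    return lookup_sequence(tokenize_and_filter(text, stopwords), table, oov_policy)
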
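"""Left-to-right Gaussian event-segmentation HMM.

Segments a neural (or model-state) trajectory into ``k`` events with
stable spatial activity patterns.  The latent chain starts in event 1,
may only stay or advance by one event per step (no skips, each event
occurs exactly once, in order), and is conditioned on ending in event
``k``.  Observations are the per-timepoint spatial patterns, z-scored
across units, modeled as isotropic Gaussians of unit variance around a
per-event mean pattern.  Fitting alternates forward-backward posterior
estimation over the chain with re-estimation of the event means
(expectation-maximization), so the log-likelihood is nondecreasing —
asserted on every fit.

The per-timepoint posterior ``gamma`` (T x k) supports both hard
boundary extraction and the co-segmentation probability between two
recordings: P(step i of A and step j of B are in the same event)
= sum_e gammaA[i, e] * gammaB[j, e], a single matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .dynamics import Trajectory

__all__ = [
    "EventSegmentation",
    "fit_event_hmm",
    "score_loglik",
    "co_segmentation_probability",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class EventSegmentation:
    """Result of fitting the event HMM at a fixed event count ``k``."""

    k: int
    gamma: np.ndarray
    boundaries: list[int]
    event_patterns: np.ndarray
    loglik: float
    n_iter: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rs = self.gamma.sum(axis=1)
        if self.gamma.size and not np.allclose(rs, 1.0, atol=1e-8):
            raise ValueError("gamma rows must sum to 1")


def _zscore_rows(X: np.ndarray) -> np.ndarray:
    """Z-score each timepoint's spatial pattern across units."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    if np.any(sd < 1e-12):
        raise ValueError(
            "trajectory has timepoints with (near-)zero spatial variance; "
            "the event model is undefined on constant patterns"
        )
    return (X - mu) / sd


def _log_emissions(Z: np.ndarray, means: np.ndarray) -> np.ndarray:
    """(T, k) log N(z_t | m_e, I) for z-scored patterns."""
    n = Z.shape[1]
    # ||z - m||^2 expanded; unit observation variance on z-scored patterns
    sq = (
        (Z * Z).sum(axis=1)[:, None]
        - 2.0 * Z @ means.T
        + (means * means).sum(axis=1)[None, :]
    )
    return -0.5 * (sq + n * _LOG2PI)


def _forward(logB: np.ndarray, log_stay: float, log_adv: float) -> np.ndarray:
    T, k = logB.shape
    alpha = np.full((T, k), -np.inf)
    alpha[0, 0] = logB[0, 0]  # chain starts in event 1
    for t in range(1, T):
        stay = alpha[t - 1] + log_stay
        adv = np.full(k, -np.inf)
        adv[1:] = alpha[t - 1, :-1] + log_adv
        alpha[t] = logB[t] + np.logaddexp(stay, adv)
    return alpha


def _backward(logB: np.ndarray, log_stay: float, log_adv: float) -> np.ndarray:
    T, k = logB.shape
    beta = np.full((T, k), -np.inf)
    beta[T - 1, k - 1] = 0.0  # chain must end in event k
    for t in range(T - 2, -1, -1):
        nxt = beta[t + 1] + logB[t + 1]
        stay = nxt + log_stay
        adv = np.full(k, -np.inf)
        adv[:-1] = nxt[1:] + log_adv
        beta[t] = np.logaddexp(stay, adv)
    return beta


def _e_step(Z: np.ndarray, means: np.ndarray) -> tuple[np.ndarray, float]:
    """Posterior event probabilities and conditional log-likelihood."""
    T, k = Z.shape[0], means.shape[0]
    logB = _log_emissions(Z, means)
    if k == 1:
        return np.ones((T, 1)), float(logB.sum())
    p_adv = (k - 1) / (T - 1)
    with np.errstate(divide="ignore"):
        log_stay, log_adv = np.log1p(-p_adv), np.log(p_adv)
    alpha = _forward(logB, log_stay, log_adv)
    beta = _backward(logB, log_stay, log_adv)
    ll = float(alpha[T - 1, k - 1])
    if not np.isfinite(ll):
        raise FloatingPointError("event HMM likelihood underflowed")
    lg = alpha + beta - ll
    gamma = np.exp(lg - logsumexp(lg, axis=1, keepdims=True))
    return gamma, ll


def _hard_boundaries(gamma: np.ndarray) -> list[int]:
    """First step of each new event under the monotone argmax assignment.

    np.argmax breaks ties toward the earlier event; the running maximum
    enforces the left-to-right structure on the hard labels.
    """
    hard = np.maximum.accumulate(gamma.argmax(axis=1))
    return [int(t) for t in range(1, len(hard)) if hard[t] > hard[t - 1]]


def _init_means(Z: np.ndarray, k: int) -> np.ndarray:
    """Means of an even split of the timeline into k contiguous chunks."""
    edges = np.linspace(0, Z.shape[0], k + 1).round().astype(int)
    return np.stack([Z[edges[e]:max(edges[e + 1], edges[e] + 1)].mean(axis=0)
                     for e in range(k)])


def fit_event_hmm(
    traj: Trajectory | np.ndarray,
    k: int,
    max_iter: int = 200,
    tol: float = 1e-4,
    seed: int = 0,
) -> EventSegmentation:
    """Fit the k-event left-to-right HMM to a trajectory.

    Parameters
    ----------
    traj:
        Trajectory (or raw ``(T, N)`` array) to segment.
    k:
        Number of events, ``1 <= k <= T``.
    max_iter, tol:
        EM stops when the log-likelihood improves by less than ``tol``
        or after ``max_iter`` iterations.
    seed:
        Accepted for interface uniformity; the fit is deterministic
        (even-split initialization).

    Returns
    -------
    EventSegmentation
        With ``gamma``, hard ``boundaries`` (0-based first step of
        events 2..k), per-event mean patterns on z-scored data, and the
        final conditional log-likelihood.
    """
    X = traj.states if isinstance(traj, Trajectory) else np.asarray(traj, float)
    T, n_units = X.shape
    if not 1 <= k <= T:
        raise ValueError(f"k must be in [1, T] = [1, {T}], got {k}")
    if n_units < 2:
        raise ValueError("need >= 2 units to z-score spatial patterns")
    Z = _zscore_rows(X)
    means = _init_means(Z, k)
    prev_ll = -np.inf
    gamma = np.ones((T, k)) / k
    ll = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        gamma, ll = _e_step(Z, means)
        if ll < prev_ll - 1e-6 * max(1.0, abs(prev_ll)):
            raise AssertionError(
                f"log-likelihood decreased ({prev_ll} -> {ll}); EM invariant violated"
            )
        if ll - prev_ll < tol:
            break
        prev_ll = ll
        # M-step: event means are gamma-weighted averages of the patterns
        w = gamma.sum(axis=0)
        new_means = means.copy()
        occupied = w > 1e-12
        new_means[occupied] = (gamma.T[occupied] @ Z) / w[occupied, None]
        means = new_means
    return EventSegmentation(
        k=k,
        gamma=gamma,
        boundaries=_hard_boundaries(gamma),
        event_patterns=means,
        loglik=ll,
        n_iter=n_iter,
        meta={"max_iter": max_iter, "tol": tol, "T": T, "n_units": n_units},
    )


def score_loglik(seg: EventSegmentation, traj: Trajectory | np.ndarray) -> float:
    """Log-likelihood of a trajectory under a fitted event model.

    Uses the same observation model and chain as fitting, so scoring the
    training trajectory returns the stored ``loglik``.
    """
    X = traj.states if isinstance(traj, Trajectory) else np.asarray(traj, float)
    if X.shape[1] != seg.event_patterns.shape[1]:
        raise ValueError(
            f"trajectory has {X.shape[1]} units but event patterns have "
            f"{seg.event_patterns.shape[1]}"
        )
    _, ll = _e_step(_zscore_rows(X), seg.event_patterns)
    return ll


def co_segmentation_probability(
    seg_a: EventSegmentation, seg_b: EventSegmentation
) -> np.ndarray:
    """P(step i of A and step j of B fall in the same event), (T_A, T_B).

    Computed as the product of the two posterior matrices,
    ``gammaA @ gammaB.T``; entries lie in [0, 1].
    """
    if seg_a.k != seg_b.k:
        raise ValueError(f"event counts differ: {seg_a.k} != {seg_b.k}")
    return seg_a.gamma @ seg_b.gamma.T
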
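"""Context construction and forgetting in paired model runs.

Two identical copies of one model (same weights, same initial state) are
driven by intact (ABCD) and scrambled (ACBD) versions of a stream.  The
elementwise difference of the two state trajectories is exactly zero
while the inputs agree (section A), jumps abruptly when they diverge
(forgetting, at ``t_forget``) and decays gradually once they agree again
(construction, from ``t_construct``) — an asymmetry inherited from leaky
integration: divergence is input-driven, convergence is memory-driven.

Per-unit half-life times of that difference after each transition give
the construction (alignment) and forgetting time constants.  Sorting
units by alignment time and cutting the order into contiguous rank bands
yields "virtual areas" — unit groups standing in for cortical regions at
different levels of the temporal hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from .dynamics import (
    HalfLifeTimes,
    IntegratorParams,
    ReservoirParams,
    Trajectory,
    half_life_times,
    run_linear_integrator,
    run_reservoir,
)
from .synthetic import StreamPair

__all__ = [
    "PairedRun",
    "TimeConstantTable",
    "VirtualArea",
    "run_paired",
    "diff_trajectory",
    "irpc",
    "alignment_time",
    "forgetting_time",
    "time_constants",
    "make_virtual_areas",
    "construct_forget_independence",
]


@dataclass
class PairedRun:
    """Trajectories of one model instance under intact and scrambled input."""

    traj_intact: Trajectory
    traj_scrambled: Trajectory
    t_forget: int
    t_construct: int

    def __post_init__(self) -> None:
        if self.traj_intact.states.shape != self.traj_scrambled.states.shape:
            raise ValueError("paired trajectories must have equal shapes")
        if not 0 < self.t_forget < self.t_construct < self.traj_intact.T:
            raise ValueError(
                f"need 0 < t_forget ({self.t_forget}) < t_construct "
                f"({self.t_construct}) < T ({self.traj_intact.T})"
            )


@dataclass
class TimeConstantTable:
    """Per-unit construction and forgetting times with censoring flags."""

    construct: HalfLifeTimes
    forget: HalfLifeTimes

    @property
    def n_units(self) -> int:
        return self.construct.times.size

    @property
    def sort_order(self) -> np.ndarray:
        """Unit indices in ascending construction-time order.

        Undefined units sort last; ties break by unit index (stable).
        """
        key = np.where(self.construct.undefined, np.inf, self.construct.times)
        return np.argsort(key, kind="stable")

    def both_defined(self) -> np.ndarray:
        return self.construct.defined() & self.forget.defined()


@dataclass
class VirtualArea:
    """A contiguous rank band of units in alignment-time order."""

    label: str
    ranks: range
    unit_ids: np.ndarray = field(default_factory=lambda: np.empty(0, int))


def run_paired(
    params: ReservoirParams | IntegratorParams,
    pair: StreamPair,
    x0: np.ndarray | None = None,
) -> PairedRun:
    """Run one model instance on both members of an intact/scrambled pair."""
    if pair.intact.T != pair.scrambled.T:
        raise ValueError("intact and scrambled streams must have equal length")
    runner = run_reservoir if isinstance(params, ReservoirParams) else run_linear_integrator
    return PairedRun(
        traj_intact=runner(params, pair.intact, x0),
        traj_scrambled=runner(params, pair.scrambled, x0),
        t_forget=pair.t_forget,
        t_construct=pair.t_construct,
    )


def diff_trajectory(run: PairedRun) -> np.ndarray:
    """Intact minus scrambled states, elementwise; (T, N)."""
    return run.traj_intact.states - run.traj_scrambled.states


def irpc(traj_a: Trajectory, traj_b: Trajectory) -> np.ndarray:
    """Inter-run pattern correlation matrix, (T_A, T_B).

    Entry (i, j) is the Pearson correlation between the spatial pattern
    at step i of run A and step j of run B, after subtracting each unit's
    temporal mean within its own run (this centering prevents a large
    shared baseline from saturating all correlations).  Patterns with
    zero spatial variance yield NaN entries rather than a silent 0.
    """
    if traj_a.N != traj_b.N:
        raise ValueError(f"unit counts differ: {traj_a.N} != {traj_b.N}")

    def _prep(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        X = X - X.mean(axis=0, keepdims=True)       # temporal mean per unit
        X = X - X.mean(axis=1, keepdims=True)       # center each pattern
        norms = np.linalg.norm(X, axis=1)
        return X, norms

    A, na = _prep(traj_a.states)
    B, nb = _prep(traj_b.states)
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (A @ B.T) / np.outer(na, nb)
    R[na < 1e-12, :] = np.nan
    R[:, nb < 1e-12] = np.nan
    return R


def alignment_time(
    diff: np.ndarray,
    t_construct: int,
    window: int | None = None,
    tolerance: float = 1e-9,
) -> HalfLifeTimes:
    """Per-unit construction (alignment) time constants.

    For each unit, the absolute intact-scrambled difference at the
    construction onset is tracked until it falls to half its initial
    value; the step count is that unit's alignment time.  Units whose
    initial difference is below ``tolerance`` are flagged undefined;
    units that never halve within the window are censored.
    """
    T = diff.shape[0]
    if window is None:
        window = T - 1 - t_construct
    if window <= 0:
        raise ValueError("window must be > 0")
    if t_construct + window > T - 1:
        raise ValueError("t_construct + window exceeds trajectory length")
    seg = np.abs(diff[t_construct:t_construct + window + 1])
    d0 = seg[0]
    undefined = d0 < tolerance
    below = seg[1:] <= 0.5 * d0[None, :]
    hit = below.any(axis=0)
    times = np.where(hit, below.argmax(axis=0) + 1, window).astype(float)
    times[undefined] = np.nan
    return HalfLifeTimes(times=times, undefined=undefined,
                         censored=~hit & ~undefined)


def forgetting_time(
    diff: np.ndarray,
    t_forget: int,
    window: int,
    tolerance: float = 1e-9,
) -> HalfLifeTimes:
    """Per-unit forgetting times: steps to rise to half the plateau.

    The plateau is each unit's mean absolute difference over the last
    quarter of the forgetting window; the forgetting time is the first
    step after ``t_forget`` at which the absolute difference reaches half
    that plateau.  Degenerate (near-zero) plateaus are flagged undefined.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    T = diff.shape[0]
    if t_forget + window > T:
        raise ValueError("t_forget + window exceeds trajectory length")
    seg = np.abs(diff[t_forget:t_forget + window])
    quarter = max(1, window // 4)
    plateau = seg[-quarter:].mean(axis=0)
    undefined = plateau < tolerance
    above = seg[1:] >= 0.5 * plateau[None, :]
    hit = above.any(axis=0)
    times = np.where(hit, above.argmax(axis=0) + 1, window).astype(float)
    times[undefined] = np.nan
    return HalfLifeTimes(times=times, undefined=undefined,
                         censored=~hit & ~undefined)


def time_constants(
    run: PairedRun,
    construct_window: int | None = None,
    forget_window: int | None = None,
    tolerance: float = 1e-9,
) -> TimeConstantTable:
    """Construction and forgetting times from one paired run.

    Default windows: construction uses everything after ``t_construct``;
    forgetting uses the scrambled period ``t_forget..t_construct``.
    """
    diff = diff_trajectory(run)
    if forget_window is None:
        forget_window = run.t_construct - run.t_forget
    return TimeConstantTable(
        construct=alignment_time(diff, run.t_construct, construct_window,
                                 tolerance),
        forget=forgetting_time(diff, run.t_forget, forget_window, tolerance),
    )


_SCHEMES = {
    # label -> (start_rank, stop_rank), 0-based into ascending alignment order
    "fast_slow_100": [("fast", 100, 200), ("slow", 800, 900)],
    "five_by_200": [(f"area{i + 1}", i * 200, (i + 1) * 200) for i in range(5)],
}


def make_virtual_areas(
    table: TimeConstantTable,
    scheme: str | list[tuple[str, int, int]] = "fast_slow_100",
) -> list[VirtualArea]:
    """Group units into virtual areas by alignment-time rank bands.

    ``fast_slow_100`` takes ranks 100-199 (fast) and 800-899 (slow);
    ``five_by_200`` partitions ranks 0-999 into five bands of 200.
    A custom scheme is a list of ``(label, start_rank, stop_rank)``.
    Ranks are positions in ascending construction-time order, not
    original unit ids.
    """
    bands = _SCHEMES[scheme] if isinstance(scheme, str) else scheme
    order = table.sort_order
    areas = []
    for label, lo, hi in bands:
        if hi > table.n_units:
            raise ValueError(
                f"scheme needs rank {hi} but only {table.n_units} units exist"
            )
        areas.append(VirtualArea(label=label, ranks=range(lo, hi),
                                 unit_ids=order[lo:hi].copy()))
    return areas


def construct_forget_independence(table: TimeConstantTable) -> tuple[float, float]:
    """Spearman correlation between construction and forgetting times.

    Computed over units where both times are defined and uncensored
    (average ranks on ties).  Requires at least 10 such units.
    """
    mask = table.both_defined()
    if mask.sum() < 10:
        raise ValueError(
            f"only {int(mask.sum())} units with both times defined; need >= 10"
        )
    res = spearmanr(table.construct.times[mask], table.forget.times[mask])
    return float(res.statistic), float(res.pvalue)
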
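"""Leaky echo-state reservoir and linear-integrator dynamics.

Both models consume an embedding stream ``u(t)`` one step per token and
emit a state trajectory.  The reservoir is a discrete-time tanh echo
state network with leak rate ``alpha``:

    x(t+1) = (1 - alpha) * x(t) + alpha * tanh(W x(t) + Win u(t))

with fixed random recurrent weights ``W`` (N x N) and input weights
``Win`` (N x K), both i.i.d. uniform on [-0.5, 0.5].  No readout is ever
trained; the object of study is the state trajectory itself.

The linear integrator baseline updates every dimension independently:

    LI(n) = (1 - alpha) * LI(n-1) + g * u(n)

with input gain ``g = 1 + alpha`` (``as_printed`` mode, the default) or
``g = alpha`` (``convex`` mode, the conventional leaky average).  The
construction/forgetting asymmetry this package studies is invariant to
that gain up to overall scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .synthetic import EmbeddingSequence

__all__ = [
    "ReservoirParams",
    "IntegratorParams",
    "Trajectory",
    "HalfLifeTimes",
    "init_reservoir",
    "run_reservoir",
    "run_linear_integrator",
    "step_response",
    "time_to_stabilize",
]

logger = logging.getLogger(__name__)

#: Initial differences below this magnitude are treated as "already at
#: asymptote" when measuring half-life times; below numeric noise for
#: tanh dynamics.
UNDEFINED_TOL = 1e-9


@dataclass
class ReservoirParams:
    """Fixed random weights and leak rate of one reservoir instance."""

    N: int
    K: int
    W: np.ndarray
    Win: np.ndarray
    alpha: float
    seed: int
    weight_range: tuple[float, float] = (-0.5, 0.5)
    spectral_radius: float | None = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.W.shape != (self.N, self.N):
            raise ValueError(f"W shape {self.W.shape} != ({self.N}, {self.N})")
        if self.Win.shape != (self.N, self.K):
            raise ValueError(f"Win shape {self.Win.shape} != ({self.N}, {self.K})")

    def measured_spectral_radius(self) -> float:
        """Spectral radius of W as stored (after any rescaling)."""
        return float(np.max(np.abs(np.linalg.eigvals(self.W))))


@dataclass
class IntegratorParams:
    """Leak rate and input-gain convention of the linear integrator."""

    alpha: float
    D: int
    input_gain_mode: str = "as_printed"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.input_gain_mode not in ("as_printed", "convex"):
            raise ValueError(f"unknown input_gain_mode {self.input_gain_mode!r}")

    @property
    def input_gain(self) -> float:
        return 1 + self.alpha if self.input_gain_mode == "as_printed" else self.alpha


@dataclass
class Trajectory:
    """A ``(T, N)`` state trajectory with provenance.

    ``states[t]`` is the state after input ``u(t)`` has been applied once.
    """

    states: np.ndarray
    model_kind: str
    params_ref: dict = field(default_factory=dict)
    input_ref: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 2:
            raise ValueError("states must be a (T, N) matrix")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("trajectory contains non-finite entries")

    @property
    def T(self) -> int:
        return self.states.shape[0]

    @property
    def N(self) -> int:
        return self.states.shape[1]


def init_reservoir(
    N: int = 1000,
    K: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    weight_range: tuple[float, float] = (-0.5, 0.5),
    spectral_radius: float | None = 1.0,
) -> ReservoirParams:
    """Draw W and Win i.i.d. uniform on ``weight_range``.

    Defaults are the standard configuration used throughout this package:
    1000 units, 100-dimensional input, leak rate 0.05.  Following echo
    state network convention (and the defaults of common reservoir
    libraries), the recurrent matrix W is rescaled so its spectral radius
    equals ``spectral_radius``; the raw uniform matrix at N = 1000 has a
    radius near 9, which drives the tanh units into saturation and
    destroys the echo-state (fading-memory) property the analyses rely
    on.  Pass ``spectral_radius=None`` to skip rescaling; the runner
    warns if trajectories saturate.
    """
    if N < 1 or K < 1:
        raise ValueError("N and K must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = weight_range
    W = rng.uniform(lo, hi, size=(N, N))
    if spectral_radius is not None:
        raw_radius = np.max(np.abs(np.linalg.eigvals(W)))
        if raw_radius > 0:
            W *= spectral_radius / raw_radius
    Win = rng.uniform(lo, hi, size=(N, K))
    return ReservoirParams(N=N, K=K, W=W, Win=Win, alpha=alpha, seed=seed,
                           weight_range=weight_range,
                           spectral_radius=spectral_radius)


def _as_matrix(stream: EmbeddingSequence | np.ndarray) -> np.ndarray:
    if isinstance(stream, EmbeddingSequence):
        return stream.matrix
    return np.asarray(stream, dtype=float)


def run_reservoir(
    params: ReservoirParams,
    stream: EmbeddingSequence | np.ndarray,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """Iterate the reservoir update over the stream, starting from ``x0``.

    Returns one state row per input row.  States stay in (-1, 1) whenever
    ``x0`` does, since each update is a convex mixture of the previous
    state and a tanh output.
    """
    U = _as_matrix(stream)
    if U.shape[1] != params.K:
        raise ValueError(f"stream dimension {U.shape[1]} != K = {params.K}")
    if not np.all(np.isfinite(U)):
        raise ValueError("input stream contains non-finite values")
    x = np.zeros(params.N) if x0 is None else np.asarray(x0, dtype=float).copy()
    if x.shape != (params.N,):
        raise ValueError(f"x0 shape {x.shape} != ({params.N},)")
    a = params.alpha
    T = U.shape[0]
    states = np.empty((T, params.N))
    for t in range(T):
        x = (1 - a) * x + a * np.tanh(params.W @ x + params.Win @ U[t])
        states[t] = x
    if T and np.max(np.abs(states)) > 0.999:
        logger.warning("reservoir trajectory near tanh saturation "
                       "(max |x| = %.4f); dynamics may be diverging",
                       np.max(np.abs(states)))
    return Trajectory(
        states,
        "reservoir",
        params_ref={"N": params.N, "K": params.K, "alpha": params.alpha,
                    "seed": params.seed},
        input_ref=dict(getattr(stream, "meta", {}) or {}),
    )


def run_linear_integrator(
    params: IntegratorParams,
    stream: EmbeddingSequence | np.ndarray,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """Leaky linear integration of the stream, dimensionwise."""
    U = _as_matrix(stream)
    if U.shape[1] != params.D:
        raise ValueError(f"stream dimension {U.shape[1]} != D = {params.D}")
    x = np.zeros(params.D) if x0 is None else np.asarray(x0, dtype=float).copy()
    if x.shape != (params.D,):
        raise ValueError(f"x0 shape {x.shape} != ({params.D},)")
    a, g = params.alpha, params.input_gain
    T = U.shape[0]
    states = np.empty((T, params.D))
    for t in range(T):
        x = (1 - a) * x + g * U[t]
        states[t] = x
    return Trajectory(
        states,
        "integrator",
        params_ref={"alpha": params.alpha, "D": params.D,
                    "input_gain_mode": params.input_gain_mode},
        input_ref=dict(getattr(stream, "meta", {}) or {}),
    )


def step_response(
    params: ReservoirParams | IntegratorParams,
    pre_len: int = 500,
    hold_len: int = 400,
    post_len: int = 600,
    hold_value: np.ndarray | float = 0.5,
    x0: np.ndarray | None = None,
) -> Trajectory:
    """Drive the model with zero / constant / zero input.

    The default lengths (500, 400, 600) give the standard diagnostic
    protocol: zero input for 500 steps, a constant vector for 400, zero
    again for 600.  Per-unit stabilization times after each transition
    reveal the distribution of effective time constants.
    """
    if min(pre_len, hold_len, post_len) < 0:
        raise ValueError("segment lengths must be >= 0")
    K = params.K if isinstance(params, ReservoirParams) else params.D
    hv = np.broadcast_to(np.asarray(hold_value, dtype=float), (K,))
    U = np.zeros((pre_len + hold_len + post_len, K))
    U[pre_len:pre_len + hold_len] = hv
    if isinstance(params, ReservoirParams):
        return run_reservoir(params, U, x0)
    return run_linear_integrator(params, U, x0)


@dataclass
class HalfLifeTimes:
    """Per-unit step counts to halve a distance, with censoring flags.

    ``times[i]`` is meaningful only where ``undefined[i]`` is False;
    censored units report the window length as a lower bound.
    """

    times: np.ndarray
    undefined: np.ndarray
    censored: np.ndarray

    def defined(self) -> np.ndarray:
        """Boolean mask of units with a finite, uncensored time."""
        return ~self.undefined & ~self.censored


def half_life_times(
    signal: np.ndarray,
    target: np.ndarray,
    window: int,
) -> HalfLifeTimes:
    """First step s >= 1 with |signal[s] - target| <= half the initial gap.

    ``signal`` is a ``(S, N)`` slice starting at the transition step
    (``signal[0]`` is the value at the transition); the search covers
    steps ``1..min(window, S-1)``.
    """
    d = np.abs(signal - target[None, :])
    d0 = d[0]
    undefined = d0 < UNDEFINED_TOL
    s_max = min(window, d.shape[0] - 1)
    below = d[1:s_max + 1] <= 0.5 * d0[None, :]
    hit = below.any(axis=0)
    first = np.where(hit, below.argmax(axis=0) + 1, window)
    censored = ~hit & ~undefined
    times = first.astype(float)
    times[undefined] = np.nan
    return HalfLifeTimes(times=times, undefined=undefined, censored=censored)


def time_to_stabilize(
    traj: Trajectory,
    transition: int,
    window: int,
) -> HalfLifeTimes:
    """Per-unit steps to halve the distance to the post-transition asymptote.

    The asymptote ``x_final`` of each unit is estimated as its mean over
    the last quarter of the window.  Units already at ``x_final`` at the
    transition (within tolerance) are flagged undefined; units that never
    halve within the window are censored at ``window``.
    """
    if window < 4:
        raise ValueError("window must be >= 4 (asymptote estimate needs "
                         "a last-quarter average)")
    if transition + window > traj.T:
        raise ValueError("transition + window exceeds trajectory length")
    seg = traj.states[transition:transition + window]
    quarter = max(1, window // 4)
    x_final = seg[-quarter:].mean(axis=0)
    return half_life_times(seg, x_final, window)
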
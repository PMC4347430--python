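"""Stochastic binary-neuron network model and event-driven simulation.

Each of the ``N`` nodes is a binary unit: active (1, an action potential plus
its refractory period) or quiescent (0).  A quiescent node activates at rate
``f(s_i)`` where ``s_i`` is its total synaptic input, and an active node
deactivates at the constant decay rate ``alpha``.  The whole network is a
continuous-time Markov jump process simulated exactly with the Gillespie
algorithm.

Units: time is milliseconds throughout, rates are ms^-1 (``alpha = 0.1 ms^-1``
corresponds to the 100 Hz decay rate used in I/O).  Node indices are 1-based
in every report, file and log; arrays are 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from numpy.typing import NDArray


class SimulationError(RuntimeError):
    """Raised when the jump-process simulation encounters invalid rates."""


class DimensionError(ValueError):
    """Raised when vector/matrix dimensions do not agree."""


@dataclass(frozen=True)
class ResponseFunctionParams:
    """Parameters of the clamped-tanh activation response.

    ``f(s) = f_max * clip(tanh(gain * (s - threshold)), 0, 1)``

    f_max caps the quiescent->active rate (ms^-1); gain sets the slope;
    threshold offsets the synaptic input at which the response turns on.
    """

    f_max: float = 0.1
    gain: float = 1.0
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if not (self.f_max > 0):
            raise ValueError(f"f_max must be > 0, got {self.f_max}")
        if not (self.gain > 0):
            raise ValueError(f"gain must be > 0, got {self.gain}")


def response_function(s, p: ResponseFunctionParams):
    """Activation rate (ms^-1) for synaptic input ``s`` (scalar or array)."""
    z = np.tanh(p.gain * (np.asarray(s, dtype=float) - p.threshold))
    out = p.f_max * np.clip(z, 0.0, 1.0)
    return float(out) if np.isscalar(s) else out


def response_slope(s, p: ResponseFunctionParams):
    """Derivative df/ds of the clamped-tanh response.

    Zero on the clamped branch (s <= threshold); on the active branch the
    tanh never reaches its upper clamp at finite s.
    """
    s_arr = np.asarray(s, dtype=float)
    z = np.tanh(p.gain * (s_arr - p.threshold))
    slope = np.where(z > 0.0, p.f_max * p.gain * (1.0 - z * z), 0.0)
    return float(slope) if np.isscalar(s) else slope


@dataclass(frozen=True)
class NetworkConfig:
    """A structural network: weights ``W`` (entry (i, j) is the effect of node
    j on node i, in synaptic-input units), per-node background input ``h``,
    decay rate ``alpha`` (ms^-1) and response parameters."""

    weights: NDArray[np.float64]
    h: NDArray[np.float64]
    alpha: float = 0.1
    f_params: ResponseFunctionParams = field(default_factory=ResponseFunctionParams)

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        h = np.asarray(self.h, dtype=float)
        object.__setattr__(self, "weights", W)
        object.__setattr__(self, "h", h)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise DimensionError(f"weights must be square, got shape {W.shape}")
        if h.shape != (W.shape[0],):
            raise DimensionError(
                f"h must have length {W.shape[0]}, got shape {h.shape}"
            )
        if not np.all(np.isfinite(W)):
            raise ValueError("weights contain non-finite entries")
        if not np.all(np.isfinite(h)):
            raise ValueError("h contains non-finite entries")
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if self.weights.shape[0] < 1:
            raise DimensionError("network must have at least one node")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def with_weights(self, weights: NDArray[np.float64]) -> "NetworkConfig":
        return replace(self, weights=np.asarray(weights, dtype=float))


def synaptic_input(weights, x, u):
    """Total synaptic input ``s_i = sum_j w_ij x_j + u_i``."""
    W = np.asarray(weights, dtype=float)
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    n = W.shape[0]
    if W.ndim != 2 or W.shape != (n, n) or x.shape != (n,) or u.shape != (n,):
        raise DimensionError(
            f"dimension mismatch: W {W.shape}, x {x.shape}, u {u.shape}"
        )
    return W @ x + u


def transition_rates(x, s, alpha: float, p: ResponseFunctionParams):
    """Per-node jump rates and their sum.

    tr_i = alpha if node i is active, else f(s_i).  Returns ``(tr, tr_net)``.
    """
    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float)
    if x.shape != s.shape:
        raise DimensionError(f"dimension mismatch: x {x.shape}, s {s.shape}")
    tr = alpha * x + response_function(s, p) * (1.0 - x)
    return tr, float(tr.sum())


@dataclass
class NetworkTrace:
    """Event record of a simulation run.

    ``states[k]`` is the node-state vector after ``event_times[k-1]``
    (``states[0]`` is the initial condition), so consecutive rows differ in
    exactly one node.  ``spike_times[i]`` holds the 0->1 transition times of
    node ``i+1`` (1-based node ids in all serialized output).
    """

    event_times: NDArray[np.float64]
    states: NDArray[np.uint8] | None
    spike_times: list[NDArray[np.float64]]
    duration: float
    inputs: NDArray[np.float64] | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.spike_times)

    @property
    def n_events(self) -> int:
        return len(self.event_times)


def gillespie_simulate(
    cfg: NetworkConfig,
    T: float,
    x0: Sequence[int] | NDArray | None = None,
    input_fn: Callable[[float], NDArray] | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    record_states: bool = True,
    record_inputs: bool = False,
) -> NetworkTrace:
    """Exact event-driven simulation of the network over ``[0, T]`` ms.

    ``input_fn(t)`` supplies the external input vector ``u`` (default: the
    constant background ``cfg.h``); it is held piecewise-constant between
    events.  At each event a single node flips with probability
    ``tr_i / tr_net`` and the waiting time is Exponential(tr_net).  If all
    rates vanish the run fast-forwards to ``T`` with no further events.
    """
    if not (T > 0):
        raise ValueError(f"duration must be > 0, got {T}")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = cfg.n_nodes
    x = np.zeros(n, dtype=float) if x0 is None else np.asarray(x0, dtype=float).copy()
    if x.shape != (n,) or not np.all((x == 0) | (x == 1)):
        raise ValueError("x0 must be a length-N binary vector")

    event_times: list[float] = []
    states: list[NDArray] | None = [x.astype(np.uint8).copy()] if record_states else None
    inputs: list[NDArray] | None = [] if record_inputs else None
    spikes: list[list[float]] = [[] for _ in range(n)]

    t = 0.0
    W = cfg.weights
    h = cfg.h
    while True:
        u = h if input_fn is None else np.asarray(input_fn(t), dtype=float)
        s = W @ x + u
        tr, tr_net = transition_rates(x, s, cfg.alpha, cfg.f_params)
        if not np.all(np.isfinite(tr)):
            bad = int(np.argmax(~np.isfinite(tr))) + 1
            raise SimulationError(f"non-finite transition rate at node {bad}")
        if tr_net <= 0.0:
            break  # absorbing: fast-forward to T
        dt = rng.exponential(1.0 / tr_net)
        if t + dt >= T:
            break
        t += dt
        i = int(np.searchsorted(np.cumsum(tr), rng.random() * tr_net, side="right"))
        i = min(i, n - 1)
        x[i] = 1.0 - x[i]
        if x[i] == 1.0:
            spikes[i].append(t)
        event_times.append(t)
        if states is not None:
            states.append(x.astype(np.uint8).copy())
        if inputs is not None:
            inputs.append(u.copy())

    return NetworkTrace(
        event_times=np.asarray(event_times, dtype=float),
        states=np.asarray(states, dtype=np.uint8) if states is not None else None,
        spike_times=[np.asarray(sp, dtype=float) for sp in spikes],
        duration=float(T),
        inputs=np.asarray(inputs, dtype=float) if inputs else None,
    )


def active_fractions(trace: NetworkTrace) -> NDArray[np.float64]:
    """Time-weighted fraction of the run each node spent active."""
    if trace.states is None:
        raise ValueError("trace was recorded without states")
    bounds = np.concatenate(([0.0], trace.event_times, [trace.duration]))
    dt = np.diff(bounds)
    return (dt[:, None] * trace.states).sum(axis=0) / trace.duration


def max_sliding_window_count(spike_times: NDArray[np.float64], window: float) -> int:
    """Maximum spike count over *all* (continuous) windows of length ``window``.

    The maximum over continuous window placements is attained by a window
    starting at a spike, so a two-pointer sweep over the sorted spikes is
    exact.
    """
    sp = np.asarray(spike_times, dtype=float)
    if sp.size == 0:
        return 0
    # count spikes in [t_i, t_i + window) for every spike i
    right = np.searchsorted(sp, sp + window, side="left")
    return int(np.max(right - np.arange(sp.size)))
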
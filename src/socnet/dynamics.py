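"""Synchronous threshold dynamics on signed networks.

Nodes carry Boolean states ``n_i(t) in {0, 1}`` and are updated in
parallel in discrete time.  In stochastic mode a node becomes active with
the Glauber probability

    P(n_i(t+1) = 1) = 1 / (1 + exp(-2 beta (f_i - theta_i - eps)))

where ``f_i = sum_j w_ij n_j(t)`` is the integer input field, ``beta`` the
inverse temperature, and ``eps in (0, 1)`` an input shift that makes the
stochastic rule reduce, as ``beta -> inf``, to the strict deterministic
threshold rule

    n_i(t+1) = 1  iff  f_i - theta_i > 0,

so nodes only become active on activating, non-zero net input.  With
``eps`` between 0 and 1, an idle node (``f_i = 0``, ``theta_i = 0``)
activates spontaneously at a small but non-zero rate — the thermal noise
that seeds activity avalanches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .network import SignedNetwork

__all__ = [
    "DynamicsState",
    "Trajectory",
    "input_field",
    "input_fields",
    "activation_probability",
    "step_stochastic",
    "step_deterministic",
    "run_window",
    "trajectory_to_events",
]


@dataclass
class DynamicsState:
    """Activity vector plus everything needed to advance it.

    One seeded generator drives a simulation; each stochastic step
    consumes exactly ``N`` uniform draws, in node-id order.
    """

    states: np.ndarray
    rng: np.random.Generator
    beta: float = 5.0
    input_shift: float = 0.5
    time: int = 0

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=bool)
        if not np.isinf(self.beta) and self.beta <= 0:
            raise ConfigError("beta must be positive (or inf)")
        if not 0.0 < self.input_shift < 1.0:
            raise ConfigError("input_shift must lie in (0, 1)")

    @classmethod
    def quiescent(cls, n_nodes: int, seed=None, beta: float = 5.0,
                  input_shift: float = 0.5) -> "DynamicsState":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return cls(states=np.zeros(n_nodes, dtype=bool), rng=rng,
                   beta=beta, input_shift=input_shift)


@dataclass
class Trajectory:
    """Boolean node-by-time activity matrix over a contiguous window."""

    window: np.ndarray  # shape (n_nodes, n_steps), bool; columns time-ordered
    start_time: int = 0

    @property
    def n_steps(self) -> int:
        return self.window.shape[1]


def input_field(net: SignedNetwork, states: np.ndarray, node: int) -> int:
    """Integer input field f_i = sum_j w_ij n_j for a single node."""
    return int(net.w[node] @ np.asarray(states, dtype=np.float64))


def input_fields(net: SignedNetwork, states: np.ndarray) -> np.ndarray:
    """Vector of input fields for all nodes (float64, integer-valued)."""
    return net.w @ np.asarray(states, dtype=np.float64)


def activation_probability(margin, beta: float) -> np.ndarray:
    """Glauber activation probability g_beta(x) = 1/(1+exp(-2 beta x))
    evaluated at margin x = f - theta - eps."""
    x = np.asarray(margin, dtype=np.float64)
    if np.isinf(beta):
        return (x > 0).astype(np.float64)
    # clip the exponent to avoid overflow warnings at large |x| beta
    z = np.clip(-2.0 * beta * x, -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(z))


def step_stochastic(net: SignedNetwork, state: DynamicsState) -> DynamicsState:
    """Advance all nodes one synchronous step of the noisy threshold rule.

    Mutates ``state`` in place (states and time) and returns it.  Exactly
    ``N`` uniforms are consumed from ``state.rng``, in node order.
    """
    if np.isinf(state.beta):
        raise ConfigError("step_stochastic requires finite beta; "
                          "use step_deterministic for the beta->inf limit")
    f = input_fields(net, state.states)
    margin = f - net.thresholds - state.input_shift
    p = activation_probability(margin, state.beta)
    draws = state.rng.random(net.n_nodes)
    state.states = draws < p
    state.time += 1
    return state


def step_deterministic(net: SignedNetwork, states: np.ndarray,
                       thresholds: np.ndarray | None = None) -> np.ndarray:
    """One synchronous step of the strict threshold rule (beta -> inf):
    node i becomes active iff f_i - theta_i > 0.

    Pure function of its inputs; ``thresholds`` overrides the network's
    own (used for fatigue-elevated effective thresholds).
    """
    theta = net.thresholds if thresholds is None else thresholds
    f = input_fields(net, states)
    return (f - theta) > 0


def run_window(net: SignedNetwork, state: DynamicsState,
               n_steps: int) -> Trajectory:
    """Apply ``n_steps`` stochastic updates, recording every state vector.

    Column ``k`` of the returned window is the state after update
    ``k + 1``; ``state`` itself ends up advanced by ``n_steps``.
    """
    if n_steps < 1:
        raise ConfigError("n_steps must be >= 1")
    start = state.time
    window = np.empty((net.n_nodes, n_steps), dtype=bool)
    for k in range(n_steps):
        step_stochastic(net, state)
        window[:, k] = state.states
    return Trajectory(window=window, start_time=start + 1)


def trajectory_to_events(traj: Trajectory):
    """Sparse event-list view of a trajectory: list of (t, node) rows for
    active entries, the TSV raster convention."""
    nodes, cols = np.nonzero(traj.window)
    ts = cols + traj.start_time
    order = np.lexsort((nodes, ts))
    return [(int(ts[k]), int(nodes[k])) for k in order]
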
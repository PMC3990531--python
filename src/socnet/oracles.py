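"""Independent oracles and deterministic toy fixtures.

Everything here is deliberately naive — literal counterfactual loops,
breadth-first propagation, direct branching-tree simulation — so the
optimized implementations elsewhere in the package can be tested against
code that shares none of their machinery.

The Galton-Watson generator doubles as the calibration standard for the
scaling statistics: a critical branching process (offspring mean 1) has
the mean-field avalanche exponents tau = 3/2, alpha = 2, gamma = 2
(theory values, used as oracle targets only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .avalanche import Avalanche
from .dynamics import step_deterministic
from .errors import ConfigError
from .network import SignedNetwork

__all__ = [
    "GWConfig",
    "gw_avalanches",
    "brute_force_branching",
    "bfs_avalanche",
    "toy_networks",
]


@dataclass
class GWConfig:
    """Binary 0-or-2 offspring branching process.

    Each individual independently has two children with probability
    ``p_two`` (offspring mean ``2 * p_two``; 0.5 is critical, 0 gives
    single-node avalanches).
    Generations are capped at ``max_generations``; capped trees are
    returned flagged so fits can exclude them.
    """

    n_avalanches: int = 10_000
    p_two: float = 0.5
    max_generations: int = 10 ** 6
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.p_two <= 1.0:
            raise ConfigError("p_two must lie in [0, 1]")
        if self.n_avalanches < 1:
            raise ConfigError("n_avalanches must be >= 1")

    @property
    def offspring_mean(self) -> float:
        return 2.0 * self.p_two


def gw_avalanches(cfg: GWConfig) -> tuple[list[Avalanche], int]:
    """Simulate independent branching trees.

    Each tree yields an :class:`Avalanche`-compatible record: size S =
    total progeny (root included), duration T = number of non-empty
    generations, profile = generation sizes.  Returns ``(avalanches,
    n_capped)``; capped trees are excluded from the returned list and
    only counted.
    """
    rng = np.random.default_rng(cfg.seed)
    out: list[Avalanche] = []
    n_capped = 0
    for _ in range(cfg.n_avalanches):
        profile = [1]
        z = 1
        while z > 0:
            if len(profile) > cfg.max_generations:
                n_capped += 1
                profile = None
                break
            z = 2 * int(rng.binomial(z, cfg.p_two))
            if z > 0:
                profile.append(z)
        if profile is None:
            continue
        prof = np.asarray(profile, dtype=np.int64)
        out.append(Avalanche(size=int(prof.sum()), duration=len(prof),
                             profile=prof, trigger=0,
                             terminated_by="natural"))
    if n_capped > 0.001 * cfg.n_avalanches:  # bias note threshold
        import warnings

        warnings.warn(
            f"{n_capped} of {cfg.n_avalanches} branching trees hit the "
            f"{cfg.max_generations}-generation cap; heavy-tail fits may "
            "be biased", stacklevel=2)
    return out, n_capped


def brute_force_branching(net: SignedNetwork, states) -> float:
    """Literal damage-spreading branching parameter.

    For every node j: flip its state, recompute the full next state
    vector with the strict deterministic rule, and count out-neighbours
    whose next state differs from the unflipped case.  O(N * N^2); test
    use only (N <= 1000).
    """
    if net.n_nodes > 1000:
        raise ConfigError("brute-force oracle is limited to N <= 1000")
    states = np.asarray(states, dtype=bool)
    base_next = step_deterministic(net, states)
    total = 0
    for j in range(net.n_nodes):
        flipped = states.copy()
        flipped[j] = ~flipped[j]
        next_flipped = step_deterministic(net, flipped)
        descendants = net.out_targets(j)
        total += int(np.sum(base_next[descendants]
                            != next_flipped[descendants]))
    return total / net.n_nodes


def bfs_avalanche(net: SignedNetwork, trigger: int) -> tuple[int, int]:
    """Breadth-first avalanche oracle for fatigue-free propagation.

    Propagates deterministically (strict threshold on the network's own
    thresholds, no exhaust) and returns (S, T).  Intended for acyclic
    fixtures where termination is guaranteed; a safety cap of N + 1
    steps guards against accidental cycles.
    """
    states = np.zeros(net.n_nodes, dtype=bool)
    states[trigger] = True
    visited = states.copy()
    steps = 1
    for _ in range(net.n_nodes + 1):
        states = step_deterministic(net, states)
        if not states.any():
            return int(visited.sum()), steps
        visited |= states
        steps += 1
    raise RuntimeError("bfs_avalanche did not terminate (cyclic fixture?)")


def toy_networks() -> dict[str, SignedNetwork]:
    """Named deterministic fixtures with hand-traceable avalanches.

    - isolated: 5 nodes, no links (any trigger: S=1, T=1)
    - chain3: 0 -> 1 -> 2 with +1 links, theta=0 (trigger 0: S=3, T=3)
    - cycle2: 0 <-> 1 with +1 links, theta=0 (period-2 limit cycle
      without exhaust)
    - tree_d3: perfect binary tree, depth 3, root 0, +1 links
      (trigger 0: S=15, T=4)
    - complete3: complete +1 digraph on 3 nodes, theta=0
    - cancel: nodes 0 (+1) and 1 (-1) both feeding node 2, theta=0
      (simultaneous activation cancels; 2 never fires)
    """
    nets: dict[str, SignedNetwork] = {}

    nets["isolated"] = SignedNetwork(5, name="isolated")

    chain = SignedNetwork(3, name="chain3")
    chain.set_link(0, 1, 1)
    chain.set_link(1, 2, 1)
    nets["chain3"] = chain

    cyc = SignedNetwork(2, name="cycle2")
    cyc.set_link(0, 1, 1)
    cyc.set_link(1, 0, 1)
    nets["cycle2"] = cyc

    depth = 3
    n_tree = 2 ** (depth + 1) - 1  # 15 nodes, root 0, children 2i+1, 2i+2
    tree = SignedNetwork(n_tree, name="tree_d3")
    for i in range((n_tree - 1) // 2):
        tree.set_link(i, 2 * i + 1, 1)
        tree.set_link(i, 2 * i + 2, 1)
    nets["tree_d3"] = tree

    comp = SignedNetwork(3, name="complete3")
    for i in range(3):
        for j in range(3):
            if i != j:
                comp.set_link(i, j, 1)
    nets["complete3"] = comp

    canc = SignedNetwork(3, name="cancel")
    canc.set_link(0, 2, 1)
    canc.set_link(1, 2, -1)
    nets["cancel"] = canc

    return nets
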
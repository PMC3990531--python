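"""Correlation-based rewiring: the self-organization engine.

The adaptive loop alternates fast node dynamics with slow topology
changes.  Each rewiring epoch picks one random node, measures the mean
lagged Pearson correlation between the node and its inputs over a
window of ``t_corr`` steps, tentatively inserts or removes one in-link
(fair coin), re-measures over another window, and keeps the change only
if the average input correlation strictly increased.  A transient of
``t_trans`` steps separates epochs, preserving a time-scale separation
of at least two orders of magnitude between node dynamics and rewiring.

The loop continuously monitors a damage-spreading branching parameter
``lambda``: the mean, over all nodes, of the number of descendants whose
next deterministic state would change if that node's current state were
flipped.  ``lambda = 1`` marks the critical point; snapshots are exported
whenever ``|lambda - 1|`` falls inside a configurable band.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, fields as dc_fields

import numpy as np
import pandas as pd

from .dynamics import (DynamicsState, Trajectory, activation_probability,
                       run_window, step_stochastic)
from .errors import ConfigError, NoCandidateSourceError, NoLinkError
from .network import (SignedNetwork, add_in_link, rebalance_link_signs,
                      remove_in_link)

__all__ = [
    "AdaptationConfig",
    "RewireTrace",
    "lagged_pearson",
    "avg_input_correlation",
    "branching_parameter",
    "evolve",
    "stimulant_experiment",
]

TRACE_COLUMNS = ["epoch", "K", "lambda", "lambda_smooth", "r_plus",
                 "action", "accepted", "node"]


@dataclass
class AdaptationConfig:
    """Parameters of the rewiring loop.

    ``t_corr`` is the correlation-measurement window (steps), ``t_trans``
    the transient between epochs; both default to 100 so that topology
    changes are at least two orders of magnitude slower than node
    updates.  ``fixed_ratio``, when set, pins the activating-link ratio
    r+ by sign flips after every epoch.  ``snapshot_band`` is the
    half-width of the ``|lambda - 1|`` band inside which snapshots of the
    current topology are collected.
    """

    n_epochs: int = 400
    t_corr: int = 100
    t_trans: int = 100
    p_activating: float = 0.5
    beta: float = 5.0
    input_shift: float = 0.5
    fixed_ratio: float | None = None
    snapshot_band: float = 0.05
    seed: int | None = None
    lambda_smooth_window: int = 10
    max_snapshots: int = 32

    def __post_init__(self):
        if self.t_corr < 2:
            raise ConfigError("t_corr must be >= 2")
        for name in ("n_epochs", "t_trans", "lambda_smooth_window",
                     "max_snapshots"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 <= self.p_activating <= 1.0:
            raise ConfigError("p_activating must lie in [0, 1]")
        if self.fixed_ratio is not None and not 0.0 < self.fixed_ratio <= 1.0:
            raise ConfigError("fixed_ratio must lie in (0, 1]")
        if self.beta <= 0:
            raise ConfigError("beta must be positive")
        if not 0.0 < self.input_shift < 1.0:
            raise ConfigError("input_shift must lie in (0, 1)")
        if self.snapshot_band < 0:
            raise ConfigError("snapshot_band must be >= 0")

    @classmethod
    def from_dict(cls, data: dict) -> "AdaptationConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "AdaptationConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def check_noise_level(self, theta: int = 0) -> float:
        """Idle-node activation probability per step; warns above 0.05.

        Thermal activation of nodes should occur at a low rate — frequent
        enough to trigger avalanches, rare enough not to dominate them.
        """
        p_idle = float(activation_probability(
            -(theta + self.input_shift), self.beta))
        if p_idle > 0.05:
            warnings.warn(
                f"idle activation probability {p_idle:.3f} > 0.05: noise "
                "may dominate the dynamics; consider a larger beta",
                stacklevel=2)
        return p_idle


class RewireTrace:
    """Per-epoch record of the adaptation run.

    Wraps a list of records exposing a :meth:`to_frame` DataFrame with
    columns epoch, K, lambda (instantaneous), lambda_smooth (running mean
    over the last ``lambda_smooth_window`` epochs), r_plus, action,
    accepted, node.
    """

    def __init__(self):
        self.records: list[dict] = []

    def append(self, **record) -> None:
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=TRACE_COLUMNS)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @staticmethod
    def frame_from_tsv(path) -> pd.DataFrame:
        return pd.read_csv(path, sep="\t")

    def column(self, name: str) -> np.ndarray:
        return np.asarray([r[name] for r in self.records])


def lagged_pearson(traj: Trajectory, target: int, source: int) -> float:
    """Pearson correlation of n_target(t+1) against n_source(t) over the
    window — one step of lag accounts for the signal transmission time.

    If either series is constant (a frozen node has zero standard
    deviation) the correlation is taken to be 0.
    """
    if traj.n_steps < 2:
        raise ConfigError("trajectory must span at least 2 steps")
    x = traj.window[source, :-1].astype(np.float64)
    y = traj.window[target, 1:].astype(np.float64)
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        return 0.0
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def avg_input_correlation(net: SignedNetwork, traj: Trajectory,
                          node: int) -> float:
    """Mean lagged correlation <C>_i of a node with its existing inputs.

    Correlations are measured only where links are present; a node
    without in-links gets 0.
    """
    sources = net.in_sources(node)
    if sources.size == 0:
        return 0.0
    y = traj.window[node, 1:].astype(np.float64)
    sy = y.std()
    if sy == 0.0:
        return 0.0
    x = traj.window[sources, :-1].astype(np.float64)
    sx = x.std(axis=1)
    cov = ((x - x.mean(axis=1, keepdims=True)) * (y - y.mean())).mean(axis=1)
    cors = np.zeros(sources.size)
    ok = sx > 0.0
    cors[ok] = cov[ok] / (sx[ok] * sy)
    return float(cors.mean())


def branching_parameter(net: SignedNetwork, states: np.ndarray) -> float:
    """Damage-spreading branching parameter lambda for the given state.

    For each node j, count the out-neighbours i whose next deterministic
    state (strict threshold rule on the *network* thresholds) would
    differ if n_j were flipped right now; lambda is the mean count over
    all N nodes.  Both the present states and the link signs enter
    through the input-field margins.
    """
    s = np.asarray(states, dtype=np.float64)
    f = net.w @ s
    margin = f - net.thresholds  # next state active iff margin > 0
    tgt, src = np.nonzero(net.w)
    if tgt.size == 0:
        return 0.0
    wl = net.w[tgt, src]
    delta = wl * (1.0 - 2.0 * s[src])  # change of f_tgt if src flips
    changed = (margin[tgt] > 0) != (margin[tgt] + delta > 0)
    return float(changed.sum()) / net.n_nodes


def _apply_action(net, node, action, p_activating, rng):
    """Perform insert/remove with infeasible-action fallback.

    The fair coin is drawn before feasibility is checked; if the chosen
    action is impossible at this node (no candidate source / no in-link)
    the other one is performed and the substitution reported.
    """
    order = [action, "remove" if action == "insert" else "insert"]
    for act in order:
        try:
            if act == "insert":
                return act, add_in_link(net, node, p_activating, rng)
            return act, remove_in_link(net, node, rng)
        except (NoCandidateSourceError, NoLinkError):
            continue
    raise ConfigError(f"node {node}: neither insertion nor removal possible")


def evolve(net: SignedNetwork, cfg: AdaptationConfig,
           theta_switch: tuple[int, int] | None = None,
           state: DynamicsState | None = None,
           ) -> tuple[SignedNetwork, RewireTrace, list[tuple[int, SignedNetwork]]]:
    """Run the adaptive rewiring loop.

    Mutates ``net`` in place and returns ``(net, trace, snapshots)``
    where ``snapshots`` is a list of ``(epoch, network copy)`` captured
    whenever the instantaneous branching parameter lies within
    ``snapshot_band`` of 1 (most recent ``max_snapshots`` kept).

    ``theta_switch = (epoch, theta)`` resets every node's activation
    threshold at the start of that epoch — the stimulant perturbation.
    An existing :class:`DynamicsState` may be passed to continue a run.
    """
    rng = np.random.default_rng(cfg.seed)
    if state is None:
        state = DynamicsState(states=np.zeros(net.n_nodes, dtype=bool),
                              rng=rng, beta=cfg.beta,
                              input_shift=cfg.input_shift)
    cfg.check_noise_level(int(net.thresholds.min()))
    trace = RewireTrace()
    snapshots: deque = deque(maxlen=cfg.max_snapshots)
    lam_hist: deque = deque(maxlen=cfg.lambda_smooth_window)

    for epoch in range(cfg.n_epochs):
        if theta_switch is not None and epoch == theta_switch[0]:
            net.thresholds[:] = theta_switch[1]
        node = int(rng.integers(net.n_nodes))
        traj_before = run_window(net, state, cfg.t_corr)
        c_before = avg_input_correlation(net, traj_before, node)
        coin = "insert" if rng.random() < 0.5 else "remove"
        action, change = _apply_action(net, node, coin, cfg.p_activating, rng)
        traj_after = run_window(net, state, cfg.t_corr)
        c_after = avg_input_correlation(net, traj_after, node)
        accepted = c_after > c_before  # ties revert
        if not accepted:
            net.revert(change)
        if cfg.fixed_ratio is not None and net.n_links > 0:
            rebalance_link_signs(net, cfg.fixed_ratio, rng)
        for _ in range(cfg.t_trans):
            step_stochastic(net, state)
        lam = branching_parameter(net, state.states)
        lam_hist.append(lam)
        trace.append(epoch=epoch, K=net.avg_connectivity, **{"lambda": lam},
                     lambda_smooth=float(np.mean(lam_hist)),
                     r_plus=net.activating_ratio, action=action,
                     accepted=bool(accepted), node=node)
        if abs(lam - 1.0) <= cfg.snapshot_band:
            snap = net.copy()
            snap.metadata.update(epoch=epoch, branching=round(lam, 6))
            snapshots.append((epoch, snap))
    return net, trace, list(snapshots)


def stimulant_experiment(net: SignedNetwork, cfg: AdaptationConfig,
                         switch_epoch: int, theta_before: int = 1,
                         theta_after: int = 0,
                         ) -> tuple[SignedNetwork, RewireTrace,
                                    list[tuple[int, SignedNetwork]]]:
    """Threshold-drop perturbation run.

    All nodes start at ``theta_before``; at ``switch_epoch`` every
    threshold is reset to ``theta_after`` in one step, mimicking a
    stimulant that raises excitability network-wide.  The rewiring loop
    is expected to respond by pruning links until the branching
    parameter returns toward 1.
    """
    if not 0 < switch_epoch < cfg.n_epochs:
        raise ConfigError("switch_epoch must fall inside the run")
    net.thresholds[:] = theta_before
    return evolve(net, cfg, theta_switch=(switch_epoch, theta_after))
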
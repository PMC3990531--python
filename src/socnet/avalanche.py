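"""Deterministic avalanche generation with threshold fatigue.

An avalanche starts from a quiescent network by activating one trigger
node, then runs the strict deterministic threshold rule until all nodes
are off again.  With parallel updates alone the dynamics could settle in
a limit cycle and never terminate, so an exhaust mechanism mimicking
neurotransmitter depletion is applied: each step, every node raises its
effective threshold by one level with probability equal to its own mean
activity over the last ``t_e`` steps of the current avalanche.  A raised
threshold stays raised until the avalanche ends (thresholds reset
between avalanches).  Any finite ``t_e`` suffices to eventually leave a
periodic attractor.

Observables per avalanche: size ``S`` (distinct nodes active at least
once), duration ``T`` (steps from first activation to the first all-off
step), and the temporal profile (number of active nodes per step).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, EmptyResultError, NonQuiescentError
from .network import SignedNetwork

__all__ = [
    "Avalanche",
    "ExhaustConfig",
    "run_avalanche",
    "run_ensemble",
    "mean_profile",
    "write_event_log",
    "write_summaries",
    "read_summaries",
]


@dataclass
class ExhaustConfig:
    """Fatigue parameters: ``t_e`` is the activity-averaging window; the
    elevation probability each step is (active steps among the last
    ``t_e``) / t_e — the denominator is always ``t_e``, so fatigue ramps
    up gently at the start of an avalanche.  ``max_steps`` is a safety
    cap — exceeding it raises rather than silently truncating."""

    t_e: int = 20
    max_steps: int = 10 ** 6

    def __post_init__(self):
        if self.t_e < 1:
            raise ConfigError("t_e must be >= 1")
        if self.max_steps < 1:
            raise ConfigError("max_steps must be >= 1")


@dataclass
class Avalanche:
    """One avalanche's record.

    ``events`` is the ordered (t, node) activation list (``None`` when
    event recording is off in bulk runs); ``profile[t]`` counts active
    nodes at step t, so ``duration == len(profile)`` and every entry is
    >= 1.  ``terminated_by`` is "exhaust" when at least one threshold
    elevation occurred before termination, else "natural".
    """

    size: int
    duration: int
    profile: np.ndarray
    trigger: int
    terminated_by: str
    events: list[tuple[int, int]] | None = None


def run_avalanche(net: SignedNetwork, trigger: int,
                  exhaust: ExhaustConfig | None = None, seed=None,
                  record_events: bool = True,
                  initial_states: np.ndarray | None = None,
                  on_cap: str = "raise") -> Avalanche:
    """Run one avalanche from ``trigger`` on a quiescent network.

    ``initial_states``, if given, must be all-off (it exists so callers
    can assert the contract explicitly).  The fatigue lottery runs after
    each state update; exactly ``N`` uniforms are drawn per step.

    Single-level fatigue guarantees termination only when input fields
    rarely exceed threshold + 1; on strongly supercritical networks
    activity can persist past ``max_steps``.  ``on_cap`` selects the
    behaviour there: "raise" (default) or "truncate", which returns the
    avalanche so far flagged ``terminated_by="cap"`` (such records must
    be excluded from scaling fits).
    """
    if on_cap not in ("raise", "truncate"):
        raise ConfigError("on_cap must be 'raise' or 'truncate'")
    exhaust = exhaust or ExhaustConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if initial_states is not None and np.any(initial_states):
        raise NonQuiescentError("avalanches must start from an all-off state")
    n = net.n_nodes
    if not 0 <= trigger < n:
        raise ConfigError(f"trigger {trigger} outside [0, {n})")

    base_theta = net.thresholds
    theta_eff = base_theta.astype(np.float64).copy()
    states = np.zeros(n, dtype=bool)
    states[trigger] = True
    visited = states.copy()
    profile = [1]
    events = [(0, trigger)] if record_events else None
    exhausted = False

    # rolling activity window for the fatigue probabilities
    history: deque = deque()
    recent = np.zeros(n, dtype=np.float64)
    history.append(states.copy())
    recent += states

    t = 0
    capped = False
    while True:
        f = net.w @ states.astype(np.float64)
        new = (f - theta_eff) > 0
        t += 1
        if t > exhaust.max_steps:
            if on_cap == "raise":
                raise RuntimeError(
                    f"avalanche exceeded {exhaust.max_steps} steps (trigger "
                    f"{trigger}); the exhaust mechanism should prevent this")
            capped = True
            break
        # fatigue: update the activity window with the new state, then
        # draw elevations (monotone within the avalanche)
        history.append(new.copy())
        recent += new
        if len(history) > exhaust.t_e:
            recent -= history.popleft()
        probs = recent / exhaust.t_e
        draws = rng.random(n)
        raise_mask = (draws < probs) & (theta_eff == base_theta)
        if raise_mask.any():
            theta_eff[raise_mask] += 1.0
            exhausted = True
        if not new.any():
            break
        profile.append(int(new.sum()))
        visited |= new
        if record_events:
            for node in np.nonzero(new)[0]:
                events.append((t, int(node)))
        states = new

    term = "cap" if capped else ("exhaust" if exhausted else "natural")
    return Avalanche(size=int(visited.sum()), duration=len(profile),
                     profile=np.asarray(profile, dtype=np.int64),
                     trigger=trigger, terminated_by=term, events=events)


def run_ensemble(net: SignedNetwork, n_avalanches: int,
                 exhaust: ExhaustConfig | None = None, seed=None,
                 record_events: bool = False,
                 on_cap: str = "raise") -> list[Avalanche]:
    """Sequential avalanches from uniformly random triggers.

    Effective thresholds and activity history reset between avalanches;
    with a fixed seed the whole ensemble is bit-reproducible.
    """
    if n_avalanches < 1:
        raise ConfigError("n_avalanches must be >= 1")
    exhaust = exhaust or ExhaustConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for _ in range(n_avalanches):
        trigger = int(rng.integers(net.n_nodes))
        out.append(run_avalanche(net, trigger, exhaust, rng,
                                 record_events=record_events, on_cap=on_cap))
    return out


def mean_profile(avalanches: list[Avalanche], duration: int,
                 n_bins: int = 25, gamma: float = 2.0,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Mean temporal profile of all duration-``T`` avalanches, rescaled
    for collapse overlay.

    Time is mapped to [0, 1] on ``n_bins`` points (linear interpolation)
    and amplitude divided by ``T**(gamma-1)``; at the collapse exponent
    the curves for different T fall onto one universal shape.  Returns
    ``(grid, scaled profile)``.
    """
    profs = [a.profile for a in avalanches if a.duration == duration]
    if not profs:
        raise EmptyResultError(f"no avalanche of duration {duration}")
    mean = np.mean(np.stack(profs), axis=0)
    grid = np.linspace(0.0, 1.0, n_bins)
    if duration == 1:
        interp = np.full(n_bins, mean[0])
    else:
        interp = np.interp(grid, np.linspace(0.0, 1.0, duration), mean)
    return grid, interp / duration ** (gamma - 1.0)


# -- event-log / summary I/O ----------------------------------------------

def write_event_log(avalanches: list[Avalanche], path) -> None:
    """TSV event log: avalanche_id, t, node (needs record_events=True)."""
    with open(path, "w") as fh:
        fh.write("avalanche_id\tt\tnode\n")
        for aid, av in enumerate(avalanches):
            if av.events is None:
                raise ConfigError(
                    "avalanche has no recorded events; rerun with "
                    "record_events=True")
            for t, node in av.events:
                fh.write(f"{aid}\t{t}\t{node}\n")


def write_summaries(avalanches: list[Avalanche], path,
                    n_nodes: int | None = None) -> None:
    """TSV summary: avalanche_id, S, T, terminated_by (+ profile as a
    comma list so shape collapse can be re-run from disk)."""
    with open(path, "w") as fh:
        if n_nodes is not None:
            fh.write(f"# n_nodes={n_nodes}\n")
        fh.write("avalanche_id\tS\tT\tterminated_by\tprofile\n")
        for aid, av in enumerate(avalanches):
            prof = ",".join(str(int(c)) for c in av.profile)
            fh.write(f"{aid}\t{av.size}\t{av.duration}\t"
                     f"{av.terminated_by}\t{prof}\n")


def read_summaries(path) -> tuple[list[Avalanche], int | None]:
    """Read a summary TSV back into Avalanche records (events dropped).
    Returns (avalanches, n_nodes from the header if present)."""
    avalanches = []
    n_nodes = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "n_nodes=" in line:
                    n_nodes = int(line.split("n_nodes=")[1])
                continue
            if line.startswith("avalanche_id\t"):
                continue
            _, s, t, term, prof = line.split("\t")
            profile = np.array([int(c) for c in prof.split(",")],
                               dtype=np.int64)
            avalanches.append(Avalanche(size=int(s), duration=int(t),
                                        profile=profile, trigger=-1,
                                        terminated_by=term))
    return avalanches, n_nodes
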
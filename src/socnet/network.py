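"""Signed directed networks of Boolean threshold nodes.

A :class:`SignedNetwork` holds ``N`` nodes coupled by asymmetric directed
links with signed unit weights ``w_ij in {+1, -1}`` (``w_ij`` is the
weight of the link from source ``j`` into target ``i``; absent pairs mean
``w_ij = 0``).  Each node carries a non-negative integer activation
threshold.  There is no underlying spatial topology: links may exist
between any ordered pair of distinct nodes.

The module also provides the elementary topology mutations used by the
adaptive rewiring loop — single-link insertion and removal (both
revertible via the :class:`LinkChange` descriptor they return) and sign
rebalancing toward a target excitatory-link ratio.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import ConfigError, NoCandidateSourceError, NoLinkError

__all__ = [
    "SignedNetwork",
    "LinkChange",
    "make_random_network",
    "add_in_link",
    "remove_in_link",
    "rebalance_link_signs",
]


@dataclass(frozen=True)
class LinkChange:
    """Descriptor of a single link mutation, sufficient to revert it.

    ``action`` is what was performed ("insert" or "remove"); reverting an
    insertion deletes the link again, reverting a removal restores the
    original weight.
    """

    action: str
    source: int
    target: int
    weight: int


class SignedNetwork:
    """Directed graph of Boolean nodes with signed unit couplings.

    Parameters
    ----------
    n_nodes:
        Number of nodes ``N``; node ids are ``0 .. N-1``.
    thresholds:
        Scalar or length-``N`` array of integer activation thresholds
        ``theta_i >= 0``.
    name:
        Free-text label carried through snapshots.
    """

    def __init__(self, n_nodes: int, thresholds: int | np.ndarray = 0,
                 name: str = "", metadata: dict | None = None):
        if n_nodes < 1:
            raise ConfigError("n_nodes must be >= 1")
        self.n_nodes = int(n_nodes)
        # Dense weight matrix: rows are targets, columns are sources.
        # Unit signed weights make float64 exact; dense keeps the
        # synchronous update a single matvec.
        self.w = np.zeros((n_nodes, n_nodes), dtype=np.float64)
        self.thresholds = np.broadcast_to(
            np.asarray(thresholds, dtype=np.int64), (n_nodes,)).copy()
        if np.any(self.thresholds < 0):
            raise ConfigError("thresholds must be >= 0")
        self.name = name
        self.metadata = dict(metadata or {})

    # -- basic observables -------------------------------------------------

    @property
    def n_links(self) -> int:
        return int(np.count_nonzero(self.w))

    @property
    def avg_connectivity(self) -> float:
        """Mean in-degree <K> = (number of links) / N."""
        return self.n_links / self.n_nodes

    @property
    def n_activating(self) -> int:
        return int(np.count_nonzero(self.w > 0))

    @property
    def activating_ratio(self) -> float:
        """Fraction r+ of links with positive sign; NaN when no links exist."""
        links = self.n_links
        if links == 0:
            return float("nan")
        return self.n_activating / links

    def in_sources(self, target: int) -> np.ndarray:
        """Node ids with a link into ``target``."""
        return np.nonzero(self.w[target])[0]

    def out_targets(self, source: int) -> np.ndarray:
        """Node ids receiving a link from ``source``."""
        return np.nonzero(self.w[:, source])[0]

    def in_degree(self, target: int) -> int:
        return int(np.count_nonzero(self.w[target]))

    def iter_links(self) -> Iterator[tuple[int, int, int]]:
        """Yield (source, target, weight) in (source, target) order."""
        tgt, src = np.nonzero(self.w)
        order = np.lexsort((tgt, src))
        for k in order:
            yield int(src[k]), int(tgt[k]), int(self.w[tgt[k], src[k]])

    # -- mutation ----------------------------------------------------------

    def set_link(self, source: int, target: int, weight: int) -> None:
        if source == target:
            raise ConfigError("self-loops are not allowed")
        if weight not in (-1, 1):
            raise ConfigError("weights must be +1 or -1")
        self.w[target, source] = weight

    def clear_link(self, source: int, target: int) -> None:
        self.w[target, source] = 0.0

    def revert(self, change: LinkChange) -> None:
        """Undo a mutation previously returned by add/remove."""
        if change.action == "insert":
            self.clear_link(change.source, change.target)
        elif change.action == "remove":
            self.set_link(change.source, change.target, change.weight)
        else:  # pragma: no cover - descriptor is produced internally
            raise ValueError(f"unknown action {change.action!r}")

    def copy(self) -> "SignedNetwork":
        dup = SignedNetwork(self.n_nodes, self.thresholds, self.name,
                            dict(self.metadata))
        dup.w = self.w.copy()
        return dup

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedNetwork):
            return NotImplemented
        return (self.n_nodes == other.n_nodes
                and np.array_equal(self.w, other.w)
                and np.array_equal(self.thresholds, other.thresholds))

    def __repr__(self) -> str:
        return (f"SignedNetwork(n_nodes={self.n_nodes}, "
                f"n_links={self.n_links}, <K>={self.avg_connectivity:.3f})")

    # -- snapshot I/O ------------------------------------------------------

    def to_tsv(self, path_or_buf) -> None:
        """Write the snapshot as a TSV edge list with a ``#`` header.

        Format: header lines ``# key=value`` (n_nodes, thresholds,
        arbitrary metadata), then one ``source<TAB>target<TAB>weight``
        row per link, sorted by (source, target).  Round-trips bit-exactly
        through :meth:`from_tsv`.
        """
        own = isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__")
        fh = open(path_or_buf, "w") if own else path_or_buf
        try:
            fh.write(f"# n_nodes={self.n_nodes}\n")
            if np.all(self.thresholds == self.thresholds[0]):
                fh.write(f"# thresholds=all:{int(self.thresholds[0])}\n")
            else:
                fh.write("# thresholds=" +
                         ",".join(str(int(t)) for t in self.thresholds) + "\n")
            if self.name:
                fh.write(f"# name={self.name}\n")
            for key, val in sorted(self.metadata.items()):
                fh.write(f"# {key}={val}\n")
            fh.write("source\ttarget\tweight\n")
            for src, tgt, wgt in self.iter_links():
                fh.write(f"{src}\t{tgt}\t{wgt}\n")
        finally:
            if own:
                fh.close()

    @classmethod
    def from_tsv(cls, path_or_buf) -> "SignedNetwork":
        own = isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__")
        fh = open(path_or_buf) if own else path_or_buf
        try:
            header: dict[str, str] = {}
            rows: list[tuple[int, int, int]] = []
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    m = re.match(r"#\s*([^=]+)=(.*)$", line)
                    if m:
                        header[m.group(1).strip()] = m.group(2)
                    continue
                if line.startswith("source\t"):
                    continue
                src_s, tgt_s, w_s = line.split("\t")
                rows.append((int(src_s), int(tgt_s), int(w_s)))
        finally:
            if own:
                fh.close()
        if "n_nodes" not in header:
            raise ConfigError("snapshot header missing n_nodes")
        n = int(header.pop("n_nodes"))
        thr_s = header.pop("thresholds", "all:0")
        if thr_s.startswith("all:"):
            thresholds: int | np.ndarray = int(thr_s[4:])
        else:
            thresholds = np.array([int(t) for t in thr_s.split(",")])
        name = header.pop("name", "")
        net = cls(n, thresholds, name=name, metadata=header)
        for src, tgt, wgt in rows:
            net.set_link(src, tgt, wgt)
        return net

    def to_tsv_string(self) -> str:
        buf = io.StringIO()
        self.to_tsv(buf)
        return buf.getvalue()

    def to_networkx(self):
        """Export as a :class:`networkx.DiGraph` with ``weight`` edge data."""
        import networkx as nx

        g = nx.DiGraph(name=self.name)
        g.add_nodes_from(range(self.n_nodes))
        for i in range(self.n_nodes):
            g.nodes[i]["threshold"] = int(self.thresholds[i])
        for src, tgt, wgt in self.iter_links():
            g.add_edge(src, tgt, weight=wgt)
        return g

    def to_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    @classmethod
    def from_graphml(cls, path) -> "SignedNetwork":
        import networkx as nx

        g = nx.read_graphml(path, node_type=int)
        n = g.number_of_nodes()
        thresholds = np.array([int(g.nodes[i].get("threshold", 0))
                               for i in range(n)])
        net = cls(n, thresholds, name=g.name or "")
        for src, tgt, data in g.edges(data=True):
            net.set_link(int(src), int(tgt), int(data["weight"]))
        return net


def make_random_network(n_nodes: int, k_init: float, p_activating: float = 0.5,
                        seed=None) -> SignedNetwork:
    """Random network at mean in-degree ``k_init``.

    ``round(N * k_init)`` links in total are placed; the integer part of
    ``k_init`` goes to every node, the remainder to a random subset, and
    each node's sources are distinct non-self nodes drawn uniformly.
    Each weight is +1 with probability ``p_activating``, else -1.
    """
    if not 0.0 <= p_activating <= 1.0:
        raise ConfigError("p_activating must lie in [0, 1]")
    if k_init < 0 or k_init > n_nodes - 1:
        raise ConfigError(
            f"k_init={k_init} outside [0, N-1]={n_nodes - 1}")
    rng = np.random.default_rng(seed)
    net = SignedNetwork(n_nodes)
    total = int(round(n_nodes * k_init))
    base, extra = divmod(total, n_nodes)
    degs = np.full(n_nodes, base, dtype=np.int64)
    if extra:
        degs[rng.choice(n_nodes, size=extra, replace=False)] += 1
    for tgt in range(n_nodes):
        k = int(degs[tgt])
        if k == 0:
            continue
        pool = np.delete(np.arange(n_nodes), tgt)
        srcs = rng.choice(pool, size=k, replace=False)
        signs = np.where(rng.random(k) < p_activating, 1, -1)
        for src, sgn in zip(srcs, signs):
            net.set_link(int(src), tgt, int(sgn))
    return net


def add_in_link(net: SignedNetwork, target: int, p_activating: float = 0.5,
                seed=None) -> LinkChange:
    """Insert one in-link at ``target`` from a uniformly drawn, previously
    unlinked non-self source; sign +1 with probability ``p_activating``.

    Mutates ``net`` in place and returns the revert descriptor.
    Raises :class:`NoCandidateSourceError` when every other node already
    links into ``target``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = net.w[target] == 0
    mask[target] = False
    candidates = np.nonzero(mask)[0]
    if candidates.size == 0:
        raise NoCandidateSourceError(
            f"node {target} already has in-links from all other nodes")
    source = int(rng.choice(candidates))
    weight = 1 if rng.random() < p_activating else -1
    net.set_link(source, target, weight)
    return LinkChange("insert", source, target, weight)


def remove_in_link(net: SignedNetwork, target: int, seed=None) -> LinkChange:
    """Delete one uniformly drawn existing in-link at ``target``.

    Mutates ``net`` in place and returns the revert descriptor.
    Raises :class:`NoLinkError` for a node without in-links.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sources = net.in_sources(target)
    if sources.size == 0:
        raise NoLinkError(f"node {target} has no in-links to remove")
    source = int(rng.choice(sources))
    weight = int(net.w[target, source])
    net.clear_link(source, target)
    return LinkChange("remove", source, target, weight)


def rebalance_link_signs(net: SignedNetwork, target_ratio: float,
                         seed=None) -> int:
    """Flip signs of random links until the activating ratio r+ is as close
    to ``target_ratio`` as integer link counts allow.

    Only signs change — link count and endpoints are conserved.  Returns
    the number of flips performed.
    """
    if not 0.0 < target_ratio <= 1.0:
        raise ConfigError("target_ratio must lie in (0, 1]")
    links = net.n_links
    if links == 0:
        raise ConfigError("cannot rebalance a network without links")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # Nearest achievable positive count given integer arithmetic.
    lo = int(np.floor(target_ratio * links))
    hi = lo + 1
    cands = [c for c in (lo, hi) if 0 <= c <= links]
    want = min(cands, key=lambda c: (abs(c / links - target_ratio), -c))
    flips = 0
    while net.n_activating != want:
        if net.n_activating < want:
            tgt_ids, src_ids = np.nonzero(net.w < 0)
        else:
            tgt_ids, src_ids = np.nonzero(net.w > 0)
        k = int(rng.integers(tgt_ids.size))
        net.w[tgt_ids[k], src_ids[k]] *= -1
        flips += 1
    return flips
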
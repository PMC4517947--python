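"""Directed-graph substrate for routing-network construction.

A :class:`RoutingNetwork` is a plain directed, unweighted graph on nodes
labelled ``0..n-1``.  Networks here are built by over-connecting and then
eliminating edges, so the structure is optimised for cheap edge removal and
repeated breadth-first routing queries rather than for generality: adjacency
is stored as per-node ``set`` objects in both directions, and node labels are
stable under every mutation (removal never relabels).

Shortest-path routing samples *uniformly* among all minimum-hop paths.  A
plain BFS would systematically prefer some paths, which would bias per-edge
usage statistics during training; uniform tie-breaking is achieved by
counting shortest paths into every node on the BFS DAG and backtracking from
the target with path-count-proportional predecessor choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RoutingNetwork",
    "UsageTable",
    "make_clique",
    "shortest_path",
    "bfs_distance",
    "read_edgelist",
    "write_edgelist",
]


class EdgelistFormatError(ValueError):
    """Raised for malformed edge-list input; message names the offending line."""


@dataclass
class RoutingNetwork:
    """Directed unweighted graph on ``n`` nodes with O(1) edge add/remove.

    Parameters
    ----------
    n : int
        Node count; nodes are labelled ``0..n-1``.
    budget : int or None
        Optional construction budget ``B`` recorded alongside the graph.
    """

    n: int
    budget: int | None = None
    out_adj: list[set[int]] = field(default_factory=list, repr=False)
    in_adj: list[set[int]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"node count must be >= 1, got {self.n}")
        if not self.out_adj:
            self.out_adj = [set() for _ in range(self.n)]
            self.in_adj = [set() for _ in range(self.n)]

    # -- mutation -----------------------------------------------------------
    def add_edge(self, u: int, v: int) -> None:
        if u == v:
            raise ValueError(f"self-loop ({u},{v}) not allowed")
        if not (0 <= u < self.n and 0 <= v < self.n):
            raise ValueError(f"edge ({u},{v}) outside node range 0..{self.n - 1}")
        self.out_adj[u].add(v)
        self.in_adj[v].add(u)

    def remove_edge(self, u: int, v: int) -> None:
        self.out_adj[u].discard(v)
        self.in_adj[v].discard(u)

    def has_edge(self, u: int, v: int) -> bool:
        return v in self.out_adj[u]

    # -- views --------------------------------------------------------------
    @property
    def num_edges(self) -> int:
        return sum(len(s) for s in self.out_adj)

    def edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u in range(self.n) for v in self.out_adj[u]]

    def copy(self) -> "RoutingNetwork":
        net = RoutingNetwork(self.n, budget=self.budget)
        net.out_adj = [set(s) for s in self.out_adj]
        net.in_adj = [set(s) for s in self.in_adj]
        return net

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RoutingNetwork):
            return NotImplemented
        return self.n == other.n and self.out_adj == other.out_adj


class UsageTable(dict):
    """Per-edge use counters: maps ``(u, v) -> nonnegative int``.

    Counts only ever increase; an entry disappears with its edge.
    """

    def increment(self, u: int, v: int, by: int = 1) -> None:
        self[(u, v)] = self.get((u, v), 0) + by


def make_clique(n: int, budget: int | None = None) -> RoutingNetwork:
    """Fully connected directed graph (all ``n(n-1)`` ordered pairs)."""
    if n < 2:
        raise ValueError(f"clique needs n >= 2, got n={n}")
    net = RoutingNetwork(n, budget=budget)
    full = set(range(n))
    net.out_adj = [full - {u} for u in range(n)]
    net.in_adj = [full - {v} for v in range(n)]
    return net


def bfs_distance(net: RoutingNetwork, s: int, t: int) -> int | None:
    """Hop distance from ``s`` to ``t``; ``None`` when unreachable."""
    if s == t:
        raise ValueError("source and target must differ")
    out_adj = net.out_adj
    if t in out_adj[s]:
        return 1
    seen = {s}
    frontier = [s]
    dist = 0
    while frontier:
        dist += 1
        nxt = []
        for u in frontier:
            for v in out_adj[u]:
                if v not in seen:
                    if v == t:
                        return dist
                    seen.add(v)
                    nxt.append(v)
        frontier = nxt
    return None


def shortest_path(
    net: RoutingNetwork,
    s: int,
    t: int,
    rng: np.random.Generator,
    priority: np.ndarray | None = None,
) -> list[int] | None:
    """A minimum-hop path ``s -> t``, or ``None`` if ``t`` is unreachable.

    With ``priority=None`` (default) the path is drawn uniformly at random
    among all minimum-hop paths: BFS records, for every node ``v`` on a
    shortest path, the number of shortest ``s -> v`` paths ``sigma[v]``;
    backtracking from ``t`` picks each predecessor ``u`` with probability
    proportional to ``sigma[u]``, which yields each full path with
    probability ``1 / sigma[t]``.

    With a ``priority`` array (a permutation of node ranks), ties are
    instead broken deterministically, emulating the consistent next-hop
    choices of a distributed routing table: the priority of a candidate
    node is mixed with the destination label, so every (node, destination)
    has a stable preference and the same (s, t) query always takes the
    same path on a given graph, while different destinations favour
    different relays.
    """
    if s == t:
        raise ValueError("source and target must differ")
    if not (0 <= s < net.n and 0 <= t < net.n):
        raise ValueError(f"pair ({s},{t}) outside node range")
    out_adj = net.out_adj
    # fast path: a direct edge is the unique minimum-hop route
    if t in out_adj[s]:
        return [s, t]

    level = {s: 0}
    sigma = {s: 1}
    preds: dict[int, list[int]] = {}
    frontier = [s]
    d = 0
    found = False
    while frontier and not found:
        d += 1
        nxt: list[int] = []
        for u in frontier:
            su = sigma[u]
            for v in out_adj[u]:
                lv = level.get(v)
                if lv is None:
                    level[v] = d
                    sigma[v] = su
                    preds[v] = [u]
                    if v == t:
                        found = True
                    else:
                        nxt.append(v)
                elif lv == d:
                    sigma[v] += su
                    preds[v].append(u)
        frontier = nxt
    if not found:
        return None

    path = [t]
    node = t
    while node != s:
        ps = preds[node]
        if len(ps) == 1:
            node = ps[0]
        elif priority is not None:
            # destination-keyed mix keeps the choice stable per (node, t)
            node = min(
                ps,
                key=lambda u: (int(priority[u]) * 2654435761 + (t + 1) * 2246822519)
                % 4294967291,
            )
        else:
            weights = np.array([sigma[u] for u in ps], dtype=float)
            node = ps[rng.choice(len(ps), p=weights / weights.sum())]
        path.append(node)
    path.reverse()
    return path


# -- edge-list I/O ----------------------------------------------------------

def write_edgelist(net: RoutingNetwork) -> str:
    """Serialise as tab-separated ``u<TAB>v`` lines (sorted, one per edge)."""
    lines = [f"# n={net.n}"]
    lines.extend(f"{u}\t{v}" for u, v in sorted(net.edges()))
    return "\n".join(lines) + "\n"


def read_edgelist(text: str, n: int | None = None) -> RoutingNetwork:
    """Parse a tab-separated edge list; inverse of :func:`write_edgelist`.

    ``#``-comment lines are skipped, except that a leading ``# n=<int>``
    header fixes the node count (needed to round-trip isolated nodes).
    Duplicate edges, self-loops and non-integer tokens raise
    :class:`EdgelistFormatError` naming the line.
    """
    edges: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    header_n = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("n=") and header_n is None:
                try:
                    header_n = int(body[2:])
                except ValueError:
                    raise EdgelistFormatError(
                        f"line {lineno}: bad node-count header {line!r}"
                    ) from None
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise EdgelistFormatError(
                f"line {lineno}: expected 'u<TAB>v', got {raw!r}"
            )
        try:
            u, v = int(parts[0]), int(parts[1])
        except ValueError:
            raise EdgelistFormatError(
                f"line {lineno}: non-integer node label in {raw!r}"
            ) from None
        if u == v:
            raise EdgelistFormatError(f"line {lineno}: self-loop ({u},{v})")
        if u < 0 or v < 0:
            raise EdgelistFormatError(f"line {lineno}: negative node label")
        if (u, v) in seen:
            raise EdgelistFormatError(f"line {lineno}: duplicate edge ({u},{v})")
        seen.add((u, v))
        edges.append((u, v))

    size = n if n is not None else header_n
    if size is None:
        size = 1 + max((max(u, v) for u, v in edges), default=0)
    net = RoutingNetwork(size)
    for u, v in edges:
        net.add_edge(u, v)
    return net
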
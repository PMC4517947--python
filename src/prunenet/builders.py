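"""Network-construction algorithms.

Four ways of arriving at a directed network with (at most) ``B`` edges while
observing an online training stream of source-target pairs:

``build_by_pruning``
    Over-connect (start from the clique), track per-edge usage along
    shortest routing paths, and iteratively eliminate the lowest-usage
    edges on a pruning-rate schedule ("use it or lose it").
``build_by_flow``
    Same elimination loop, but usage comes from a biologically more
    plausible flow model: each edge independently fails with probability
    ``fail_prob`` per signalling episode, and every surviving edge lying on
    a surviving source-to-target route is rewarded.
``build_by_growing``
    The engineering baseline: start from a random spanning-tree backbone
    and add the most-demanded distance-2 shortcut edges along observed
    routes, in per-block installments.
``build_no_learning``
    ``B`` uniformly random directed edges; ignores the training data.

All algorithms consume an explicit numpy Generator; identical seeds and
configurations reproduce identical traces.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .distributions import PairDistribution, sample_pairs
from .graph_core import RoutingNetwork, UsageTable, make_clique, shortest_path
from .schedules import PruneSchedule

__all__ = [
    "BuildTrace",
    "IntervalRecord",
    "build_by_pruning",
    "build_by_flow",
    "build_by_growing",
    "build_no_learning",
    "route_and_record",
]


@dataclass
class IntervalRecord:
    """Per-interval bookkeeping for one construction run."""

    index: int
    edges_before: int
    edges_removed: int
    edges_added: int
    edges_after: int
    usage_total: int
    usage_max: int
    skipped_pairs: int


@dataclass
class BuildTrace:
    """Result of one construction run: final network plus per-interval log."""

    algorithm: str
    network: RoutingNetwork
    intervals: list[IntervalRecord] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def edge_counts(self) -> list[int]:
        return [rec.edges_after for rec in self.intervals]

    @property
    def energy(self) -> int:
        """Cumulative edges maintained across intervals (edge-intervals)."""
        return sum(rec.edges_before for rec in self.intervals)

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "config": self.config,
            "final_edges": self.network.num_edges,
            "intervals": [vars(rec) for rec in self.intervals],
        }


def route_and_record(
    net: RoutingNetwork,
    usage: UsageTable,
    s: int,
    t: int,
    rng: np.random.Generator,
    priority: np.ndarray | None = None,
) -> int | None:
    """Route one pair along a shortest path and increment the usage of every
    edge on it.  Returns the hop count, or ``None`` (and records nothing)
    when the target is unreachable.  ``priority`` selects consistent
    routing-table tie-breaking; ``None`` samples uniformly."""
    path = shortest_path(net, s, t, rng, priority)
    if path is None:
        return None
    for u, v in zip(path, path[1:]):
        usage.increment(u, v)
    return len(path) - 1


def _route_priority(
    route_policy: str, n: int, rng: np.random.Generator
) -> np.ndarray | None:
    """Per-build routing-table tie-break order (None = uniform sampling)."""
    if route_policy == "table":
        return rng.permutation(n)
    if route_policy == "uniform":
        return None
    raise ValueError(f"unknown route_policy {route_policy!r}")


def _blocks(p: int, K: int) -> list[int]:
    """Split p training pairs into K blocks; the last absorbs the remainder."""
    sizes = [p // K] * K
    sizes[-1] += p % K
    return sizes


def _prune_lowest_usage(
    net: RoutingNetwork, usage: UsageTable, count: int, rng: np.random.Generator
) -> None:
    """Remove ``count`` edges of lowest usage, ties broken uniformly."""
    if count <= 0:
        return
    edges = net.edges()
    counts = np.fromiter(
        (usage.get(e, 0) for e in edges), dtype=np.int64, count=len(edges)
    )
    order = np.lexsort((rng.random(len(edges)), counts))
    for idx in order[:count]:
        u, v = edges[idx]
        net.remove_edge(u, v)
        usage.pop((u, v), None)


def _check_prune_args(n: int, B: int, schedule: PruneSchedule, p: int) -> None:
    E0 = n * (n - 1)
    if not (0 < B < E0):
        raise ValueError(f"budget must satisfy 0 < B < n(n-1); got B={B}, n={n}")
    if schedule.E0 != E0 or schedule.B != B:
        raise ValueError("schedule was solved for a different (E0, B)")
    if p < 1:
        raise ValueError("training stream must be non-empty")


def build_by_pruning(
    dist: PairDistribution,
    n: int,
    B: int,
    schedule: PruneSchedule,
    p: int,
    rng: np.random.Generator,
    route_policy: str = "table",
) -> BuildTrace:
    """Construct a network by usage-tracked pruning from the clique.

    Each of ``p`` training pairs is routed via a shortest path and every
    edge on that path gains one usage count (initially all
    routes are the direct source-target edges).  After each of the ``K``
    blocks of pairs, the schedule's removal count of lowest-usage edges is
    eliminated (random tie-breaking).  Usage is cumulative across intervals.
    Unroutable training pairs contribute no usage and are skipped.

    ``route_policy='table'`` (default) breaks shortest-path ties with a
    per-build random node-priority order mixed with the destination label,
    emulating distributed routing tables: each (node, destination) has a
    stable next hop, so the same (s, t) always routes identically on a
    given graph and usage concentrates on a stable backbone.
    ``route_policy='uniform'`` instead samples uniformly among minimum-hop
    paths per query, which spreads usage across all alternatives and yields
    markedly more fragmented sparse networks.
    """
    _check_prune_args(n, B, schedule, p)
    priority = _route_priority(route_policy, n, rng)
    net = make_clique(n, budget=B)
    usage = UsageTable()
    stream = sample_pairs(dist, p, rng)
    removals = schedule.removal_counts()
    trace = BuildTrace(
        "prune",
        net,
        config={
            "n": n,
            "B": B,
            "p": p,
            "K": schedule.K,
            "shape": schedule.shape,
            "route_policy": route_policy,
        },
    )
    pos = 0
    for i, block in enumerate(_blocks(p, schedule.K)):
        skipped = 0
        before = net.num_edges
        for s, t in stream[pos : pos + block]:
            if route_and_record(net, usage, int(s), int(t), rng, priority) is None:
                skipped += 1
        pos += block
        _prune_lowest_usage(net, usage, removals[i], rng)
        trace.intervals.append(
            IntervalRecord(
                index=i,
                edges_before=before,
                edges_removed=removals[i],
                edges_added=0,
                edges_after=net.num_edges,
                usage_total=sum(usage.values()),
                usage_max=max(usage.values(), default=0),
                skipped_pairs=skipped,
            )
        )
    return trace


def _flow_reward_edges(
    edges: list[tuple[int, int]],
    alive: np.ndarray,
    n: int,
    s: int,
    t: int,
) -> list[int]:
    """Indices of surviving edges lying on a surviving s -> t route.

    An edge qualifies when its tail is reachable from ``s`` and its head
    co-reaches ``t`` in the surviving subgraph with in-edges of ``s`` and
    out-edges of ``t`` deleted (so routes never re-enter the source or
    leave the target).
    """
    out_adj: list[list[int]] = [[] for _ in range(n)]
    in_adj: list[list[int]] = [[] for _ in range(n)]
    live_idx = np.flatnonzero(alive)
    for idx in live_idx:
        u, v = edges[idx]
        if v == s or u == t:
            continue
        out_adj[u].append(v)
        in_adj[v].append(u)

    def reach(adj: list[list[int]], root: int) -> np.ndarray:
        seen = np.zeros(n, dtype=bool)
        seen[root] = True
        stack = [root]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        return seen

    fwd = reach(out_adj, s)
    if not fwd[t]:
        return []
    bwd = reach(in_adj, t)
    rewarded = []
    for idx in live_idx:
        u, v = edges[idx]
        if v == s or u == t:
            continue
        if fwd[u] and bwd[v]:
            rewarded.append(int(idx))
    return rewarded


def build_by_flow(
    dist: PairDistribution,
    n: int,
    B: int,
    schedule: PruneSchedule,
    p: int,
    rng: np.random.Generator,
    fail_prob: float = 0.65,
) -> BuildTrace:
    """Construct a network under the flow/BFS activity model.

    Per training pair, every edge independently survives the episode with
    probability ``1 - fail_prob`` (default failure probability 0.65,
    mimicking synaptic transmission failure); each surviving edge that lies
    on at least one surviving source-to-target route is rewarded with one
    usage count.  Pruning then proceeds exactly as in
    :func:`build_by_pruning`.
    """
    if not (0.0 <= fail_prob < 1.0):
        raise ValueError(f"fail_prob must be in [0, 1), got {fail_prob}")
    _check_prune_args(n, B, schedule, p)
    net = make_clique(n, budget=B)
    usage = UsageTable()
    stream = sample_pairs(dist, p, rng)
    removals = schedule.removal_counts()
    trace = BuildTrace(
        "flow",
        net,
        config={
            "n": n,
            "B": B,
            "p": p,
            "K": schedule.K,
            "shape": schedule.shape,
            "fail_prob": fail_prob,
        },
    )
    keep = 1.0 - fail_prob
    pos = 0
    for i, block in enumerate(_blocks(p, schedule.K)):
        edges = net.edges()
        m = len(edges)
        skipped = 0
        before = net.num_edges
        for s, t in stream[pos : pos + block]:
            alive = rng.random(m) < keep
            rewarded = _flow_reward_edges(edges, alive, n, int(s), int(t))
            if not rewarded:
                skipped += 1
            for idx in rewarded:
                usage.increment(*edges[idx])
        pos += block
        _prune_lowest_usage(net, usage, removals[i], rng)
        trace.intervals.append(
            IntervalRecord(
                index=i,
                edges_before=before,
                edges_removed=removals[i],
                edges_added=0,
                edges_after=net.num_edges,
                usage_total=sum(usage.values()),
                usage_max=max(usage.values(), default=0),
                skipped_pairs=skipped,
            )
        )
    return trace


def _random_spanning_tree(n: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Uniform random labelled tree on n nodes via a random Pruefer sequence."""
    import heapq

    if n < 2:
        raise ValueError("spanning tree needs n >= 2")
    if n == 2:
        return [(0, 1)]
    seq = [int(x) for x in rng.integers(0, n, size=n - 2)]
    degree = [1] * n
    for x in seq:
        degree[x] += 1
    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    edges = []
    for x in seq:
        leaf = heapq.heappop(leaves)
        edges.append((leaf, x))
        degree[leaf] = 0
        degree[x] -= 1
        if degree[x] == 1:
            heapq.heappush(leaves, x)
    u, v = [i for i in range(n) if degree[i] == 1]
    edges.append((u, v))
    return edges


def build_by_growing(
    dist: PairDistribution,
    n: int,
    B: int,
    p: int,
    rng: np.random.Generator,
    K: int = 10,
    route_policy: str = "table",
    tree: list[tuple[int, int]] | None = None,
) -> BuildTrace:
    """Grow a network from a spanning-tree backbone by adding shortcuts.

    A uniformly random undirected spanning tree is installed as ``2(n-1)``
    directed arcs, guaranteeing every pair is routable.  Training pairs are
    processed in ``K`` blocks; each routed pair accumulates shortcut demand
    for every ordered node pair at distance 2 along its route, and after
    each block the highest-demand absent arcs (ties random) are added in
    equal installments until the budget ``B`` is reached.
    """
    if B < 2 * (n - 1):
        raise ValueError(
            f"growing needs B >= 2(n-1) for the doubled spanning tree; "
            f"got B={B}, n={n}"
        )
    if p < 1:
        raise ValueError("training stream must be non-empty")
    priority = _route_priority(route_policy, n, rng)
    net = RoutingNetwork(n, budget=B)
    if tree is None:
        tree = _random_spanning_tree(n, rng)  # uniform over labelled trees
    elif len(tree) != n - 1:
        raise ValueError("supplied tree must have n-1 undirected edges")
    for u, v in tree:
        net.add_edge(u, v)
        net.add_edge(v, u)

    extra = B - net.num_edges
    base, rem = divmod(extra, K)
    installments = [base + (1 if i < rem else 0) for i in range(K)]

    demand: Counter[tuple[int, int]] = Counter()
    stream = sample_pairs(dist, p, rng)
    trace = BuildTrace(
        "grow", net, config={"n": n, "B": B, "p": p, "K": K}
    )
    pos = 0
    deficit = 0
    for i, block in enumerate(_blocks(p, K)):
        before = net.num_edges
        for s, t in stream[pos : pos + block]:
            path = shortest_path(net, int(s), int(t), rng, priority)
            if path is None:  # cannot happen on a tree-containing graph
                continue
            for a, b in zip(path, path[2:]):
                demand[(a, b)] += 1
        pos += block
        want = installments[i] + deficit
        added = 0
        if want > 0 and demand:
            cands = [e for e in demand if not net.has_edge(*e)]
            if cands:
                keys = np.lexsort(
                    (
                        rng.random(len(cands)),
                        np.array([-demand[e] for e in cands]),
                    )
                )
                for idx in keys[:want]:
                    net.add_edge(*cands[idx])
                    added += 1
        deficit = want - added
        trace.intervals.append(
            IntervalRecord(
                index=i,
                edges_before=before,
                edges_removed=0,
                edges_added=added,
                edges_after=net.num_edges,
                usage_total=sum(demand.values()),
                usage_max=max(demand.values(), default=0),
                skipped_pairs=0,
            )
        )
    return trace


def build_no_learning(n: int, B: int, rng: np.random.Generator) -> BuildTrace:
    """``B`` distinct directed edges drawn uniformly without replacement."""
    total = n * (n - 1)
    if not (0 < B <= total):
        raise ValueError(f"need 0 < B <= n(n-1), got B={B}, n={n}")
    idx = rng.choice(total, size=B, replace=False)
    net = RoutingNetwork(n, budget=B)
    for k in idx:
        u, r = divmod(int(k), n - 1)
        v = r if r < u else r + 1
        net.add_edge(u, v)
    trace = BuildTrace("random", net, config={"n": n, "B": B})
    trace.intervals.append(
        IntervalRecord(0, B, 0, B, B, 0, 0, 0)
    )
    return trace
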
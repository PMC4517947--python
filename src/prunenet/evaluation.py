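"""Test-phase metrics for a fixed network.

During testing the network is frozen and a fresh stream of source-target
pairs is drawn from the same distribution used for training.  Four numbers
summarise a constructed network:

efficiency
    Mean shortest-path hop distance over the test pairs; disconnected
    pairs incur a fixed penalty distance (default ``2n``, which exceeds
    any possible path length).  Lower is better.
robustness
    Mean count of short routes per pair, found by iteratively removing the
    interior nodes of each discovered shortest path (or the edge itself
    for a 1-hop path) and re-searching, accepting routes at most ``slack``
    hops longer than the original shortest path.  Higher is better.  By
    default the primary shortest path itself is counted, so a connected
    pair scores at least 1; ``count_primary=False`` counts the surviving
    alternatives only.
unroutable
    Number of test pairs with no directed path at all.
energy
    Cumulative edges maintained during construction (from the build trace).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .builders import BuildTrace
from .graph_core import RoutingNetwork, bfs_distance

__all__ = ["EvaluationReport", "efficiency", "robustness", "unroutable", "evaluate"]


@dataclass
class EvaluationReport:
    efficiency: float
    robustness: float
    unroutable: int
    energy: int
    penalty: float
    test_pairs: int
    robustness_slack: int = 1
    robustness_counts_primary: bool = True

    def to_dict(self) -> dict:
        return asdict(self)


def efficiency(
    net: RoutingNetwork, test: np.ndarray, penalty: float | None = None
) -> float:
    """Mean shortest-path distance over test pairs (penalty if disconnected)."""
    if len(test) == 0:
        raise ValueError("test stream is empty")
    if penalty is None:
        penalty = 2 * net.n
    if penalty < 1:
        raise ValueError(f"penalty must be a positive distance, got {penalty}")
    total = 0.0
    for s, t in test:
        d = bfs_distance(net, int(s), int(t))
        total += penalty if d is None else d
    return total / len(test)


def _lex_shortest_path(
    out_adj: list[set[int]],
    s: int,
    t: int,
    dead: set[int],
    dead_edges: set[tuple[int, int]],
) -> list[int] | None:
    """Deterministic (lexicographically smallest) shortest path s -> t,
    avoiding removed nodes and removed edges."""
    n = len(out_adj)
    dist_to_t = [-1] * n
    dist_to_t[t] = 0
    # reverse BFS from t over the surviving subgraph
    in_lists: list[list[int]] = [[] for _ in range(n)]
    for u in range(n):
        if u != t and u in dead:
            continue
        for v in out_adj[u]:
            if (v == s) or (v != t and v in dead) or ((u, v) in dead_edges):
                continue
            in_lists[v].append(u)
    frontier = [t]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for v in frontier:
            for u in in_lists[v]:
                if dist_to_t[u] == -1:
                    dist_to_t[u] = d
                    nxt.append(u)
        frontier = nxt
    if dist_to_t[s] == -1:
        return None
    # greedy forward walk: smallest next node that still decreases distance
    path = [s]
    node = s
    while node != t:
        want = dist_to_t[node] - 1
        nxt_node = min(
            v
            for v in out_adj[node]
            if dist_to_t[v] == want
            and (v == t or v not in dead)
            and v != s
            and (node, v) not in dead_edges
        )
        path.append(nxt_node)
        node = nxt_node
    return path


def _pair_route_count(
    net: RoutingNetwork, s: int, t: int, slack: int, count_primary: bool
) -> int:
    """Iterative alternative-route count for one pair (0 if disconnected)."""
    dead: set[int] = set()
    dead_edges: set[tuple[int, int]] = set()
    primary = _lex_shortest_path(net.out_adj, s, t, dead, dead_edges)
    if primary is None:
        return 0
    d0 = len(primary) - 1
    count = 0
    path = primary
    while path is not None and len(path) - 1 <= d0 + slack:
        count += 1
        if len(path) == 2:  # direct edge: no interior nodes, remove the edge
            dead_edges.add((path[0], path[1]))
        else:
            dead.update(path[1:-1])
        path = _lex_shortest_path(net.out_adj, s, t, dead, dead_edges)
    if not count_primary:
        count -= 1
    return count


def robustness(
    net: RoutingNetwork,
    test: np.ndarray,
    slack: int = 1,
    count_primary: bool = True,
) -> float:
    """Mean number of short routes per test pair.

    For each pair with shortest distance ``d0`` the search repeatedly finds
    a shortest path, counts it while its length is at most ``d0 + slack``,
    and removes its interior nodes (or, for a direct edge, the edge itself)
    before searching again.  Disconnected pairs score 0.
    """
    if len(test) == 0:
        raise ValueError("test stream is empty")
    total = 0
    for s, t in test:
        total += _pair_route_count(net, int(s), int(t), slack, count_primary)
    return total / len(test)


def unroutable(net: RoutingNetwork, test: np.ndarray) -> int:
    """Count of test pairs with no directed path."""
    return sum(1 for s, t in test if bfs_distance(net, int(s), int(t)) is None)


def evaluate(
    trace: BuildTrace,
    test: np.ndarray,
    penalty: float | None = None,
    slack: int = 1,
    count_primary: bool = True,
) -> EvaluationReport:
    """Bundle all test-phase metrics for one constructed network."""
    net = trace.network
    if penalty is None:
        penalty = 2 * net.n
    return EvaluationReport(
        efficiency=efficiency(net, test, penalty),
        robustness=robustness(net, test, slack, count_primary),
        unroutable=unroutable(net, test),
        energy=trace.energy,
        penalty=penalty,
        test_pairs=len(test),
        robustness_slack=slack,
        robustness_counts_primary=count_primary,
    )
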
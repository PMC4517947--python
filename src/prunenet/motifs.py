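"""Triad (3-node motif) census and over-representation statistics.

Constructed networks are screened for non-random local structure by
counting all 16 directed triad isomorphism classes (standard triad-census
nomenclature: '003' ... '300') and comparing each count against a null
ensemble of randomized networks.  The default null model preserves every
node's in- and out-degree via repeated two-edge swaps
((a,b),(c,d) -> (a,d),(c,b)); a uniform fixed-edge-count G(n, m) null is
available as an option and as the automatic fallback when a network is too
sparse to swap.

The feed-forward loop is triad class '030T' (arcs a->b, a->c, b->c with no
reciprocation), the motif classically over-represented in signal-processing
networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import networkx as nx
import numpy as np

from .graph_core import RoutingNetwork

TRIAD_CLASSES = (
    "003", "012", "102", "021D", "021U", "021C", "111D", "111U",
    "030T", "030C", "201", "120D", "120U", "120C", "210", "300",
)
FEED_FORWARD = "030T"

__all__ = [
    "MotifCensus",
    "MotifReport",
    "triad_census",
    "motif_zscores",
    "TRIAD_CLASSES",
    "FEED_FORWARD",
]


@dataclass
class MotifCensus:
    counts: dict[str, int]
    n_triples: int


@dataclass
class MotifReport:
    """Per-class observed counts versus a randomized ensemble.

    ``zscores[c]`` is ``(observed - mean) / sd``; classes whose ensemble
    standard deviation is zero are listed in ``degenerate`` and carry a
    ``None`` Z-score.  ``pvalues`` are one-sided empirical (fraction of
    ensemble counts >= observed, with the +1 continuity correction).
    """

    observed: dict[str, int]
    ensemble_mean: dict[str, float]
    ensemble_sd: dict[str, float]
    zscores: dict[str, float | None]
    pvalues: dict[str, float]
    degenerate: list[str]
    ensemble_size: int
    null_model: str

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "ensemble_mean": self.ensemble_mean,
            "ensemble_sd": self.ensemble_sd,
            "zscores": self.zscores,
            "pvalues": self.pvalues,
            "degenerate": self.degenerate,
            "ensemble_size": self.ensemble_size,
            "null_model": self.null_model,
        }


def _to_nx(net: RoutingNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(range(net.n))
    g.add_edges_from(net.edges())
    return g


def triad_census(net: RoutingNetwork) -> MotifCensus:
    """Exact counts of all 16 triad classes over the C(n,3) node triples."""
    if net.n < 3:
        raise ValueError(f"triad census needs n >= 3, got n={net.n}")
    counts = nx.triadic_census(_to_nx(net))
    return MotifCensus(
        counts={c: int(counts[c]) for c in TRIAD_CLASSES},
        n_triples=comb(net.n, 3),
    )


def _census_of_edges(n: int, edges: list[tuple[int, int]]) -> dict[str, int]:
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return {c: int(v) for c, v in nx.triadic_census(g).items()}


def degree_preserving_swap(
    edges: list[tuple[int, int]],
    rng: np.random.Generator,
    attempts: int,
) -> list[tuple[int, int]]:
    """Randomize an edge list by two-edge swaps preserving in/out degrees.

    Each attempt picks two edges (a,b), (c,d) and rewires to (a,d), (c,b)
    when that creates neither self-loops nor duplicate edges.
    """
    edges = list(edges)
    edge_set = set(edges)
    m = len(edges)
    if m < 2:
        return edges
    picks = rng.integers(0, m, size=(attempts, 2))
    for i, j in picks:
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if a == d or c == b:
            continue
        if (a, d) in edge_set or (c, b) in edge_set:
            continue
        edge_set.remove((a, b))
        edge_set.remove((c, d))
        edge_set.add((a, d))
        edge_set.add((c, b))
        edges[i] = (a, d)
        edges[j] = (c, b)
    return edges


def _swappable(edges: list[tuple[int, int]], rng: np.random.Generator) -> bool:
    """Cheap probe: can any of 200 random attempts perform a legal swap?"""
    edge_set = set(edges)
    m = len(edges)
    if m < 2:
        return False
    for i, j in rng.integers(0, m, size=(200, 2)):
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if a != d and c != b and (a, d) not in edge_set and (c, b) not in edge_set:
            return True
    return False


def motif_zscores(
    net: RoutingNetwork,
    ensemble_size: int = 1000,
    rng: np.random.Generator | None = None,
    null_model: str = "swap",
    swaps_per_edge: int = 100,
) -> MotifReport:
    """Triad-class Z-scores against a randomized network ensemble.

    Each ensemble member is an independent randomization of the input:
    either ``swaps_per_edge * |E|`` attempted degree-preserving edge swaps
    (``null_model='swap'``, the default) or a uniform directed G(n, m)
    graph with the same edge count (``null_model='gnm'``).
    """
    if ensemble_size < 100:
        raise ValueError(f"ensemble_size must be >= 100, got {ensemble_size}")
    if null_model not in ("swap", "gnm"):
        raise ValueError(f"unknown null model {null_model!r}")
    rng = np.random.default_rng() if rng is None else rng
    n = net.n
    edges = net.edges()
    m = len(edges)

    used_null = null_model
    if null_model == "swap" and not _swappable(edges, rng):
        used_null = "gnm"  # too sparse/constrained to swap

    observed = triad_census(net).counts
    samples = np.zeros((ensemble_size, len(TRIAD_CLASSES)), dtype=np.int64)
    attempts = swaps_per_edge * m
    total_pairs = n * (n - 1)
    for k in range(ensemble_size):
        if used_null == "swap":
            rand_edges = degree_preserving_swap(edges, rng, attempts)
        else:
            idx = rng.choice(total_pairs, size=m, replace=False)
            rand_edges = []
            for e in idx:
                u, r = divmod(int(e), n - 1)
                rand_edges.append((u, r if r < u else r + 1))
        cen = _census_of_edges(n, rand_edges)
        samples[k] = [cen[c] for c in TRIAD_CLASSES]

    mean = samples.mean(axis=0)
    sd = samples.std(axis=0, ddof=1)
    obs_vec = np.array([observed[c] for c in TRIAD_CLASSES])
    pvals = (1 + (samples >= obs_vec).sum(axis=0)) / (ensemble_size + 1)

    zscores: dict[str, float | None] = {}
    degenerate: list[str] = []
    for i, c in enumerate(TRIAD_CLASSES):
        if sd[i] == 0:
            zscores[c] = None
            degenerate.append(c)
        else:
            zscores[c] = float((obs_vec[i] - mean[i]) / sd[i])
    return MotifReport(
        observed=observed,
        ensemble_mean={c: float(mean[i]) for i, c in enumerate(TRIAD_CLASSES)},
        ensemble_sd={c: float(sd[i]) for i, c in enumerate(TRIAD_CLASSES)},
        zscores=zscores,
        pvalues={c: float(pvals[i]) for i, c in enumerate(TRIAD_CLASSES)},
        degenerate=degenerate,
        ensemble_size=ensemble_size,
        null_model=used_null,
    )
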
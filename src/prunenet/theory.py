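"""Three-parameter random-graph theory of pruned networks.

Final networks trained under the 2-patch distribution are approximated by a
directed Erdos-Renyi ensemble with class-specific edge probabilities: edges
within the source half or within the target half exist independently with
probability ``p``, source-to-target edges with probability ``q``, and
target-to-source edges with probability ``z`` (``z -> 0`` in optimal sparse
networks, since such edges never lie on short source-target routes).

Two mean-field computations are provided:

``expected_efficiency``
    Expected source-target shortest-path distance in the ensemble via a
    hop-layer (annealed BFS) recursion.  The one- and two-hop terms are
    exact for independent edges; deeper layers use the standard
    independent-neighbourhood approximation.  Disconnection mass is
    penalty-weighted exactly as in test-phase evaluation.

``predict_pq``
    A mean-field interval recurrence tracking the three class densities
    through a pruning schedule.  Per interval, expected per-edge usage of
    each class is derived from the routing model (direct source-target
    edges absorb single-hop traffic; as ``q`` falls, two-hop routes
    crossing one within-class and one cross-class edge absorb it);
    within-class usage is modelled as Poisson, and the schedule's removal
    count is taken from the lowest cumulative-usage level upward, pro-rata
    across classes within a level (mirroring lowest-usage-first pruning
    with random tie-breaking at the ensemble level).  This recurrence is a
    calibrated surrogate validated against the full simulator, not a
    closed-form derivation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import poisson

from .graph_core import RoutingNetwork
from .schedules import PruneSchedule

__all__ = ["ERTriple", "sample_er", "expected_efficiency", "predict_pq"]


@dataclass
class ERTriple:
    """Class edge probabilities of the two-patch directed ensemble."""

    p: float
    q: float
    z: float
    n: int

    def __post_init__(self) -> None:
        for name in ("p", "q", "z"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n < 2:
            raise ValueError(f"need n >= 2, got {self.n}")

    @property
    def n_sources(self) -> int:
        return (self.n + 1) // 2

    @property
    def n_targets(self) -> int:
        return self.n - self.n_sources


def sample_er(triple: ERTriple, rng: np.random.Generator) -> RoutingNetwork:
    """Draw one network: each candidate edge present independently with its
    class probability (p within halves, q source->target, z target->source)."""
    n, nS = triple.n, triple.n_sources
    net = RoutingNetwork(n)
    is_src = np.zeros(n, dtype=bool)
    is_src[:nS] = True
    prob = np.where(
        is_src[:, None] == is_src[None, :],
        triple.p,
        np.where(is_src[:, None], triple.q, triple.z),
    )
    np.fill_diagonal(prob, 0.0)
    present = rng.random((n, n)) < prob
    for u, v in zip(*np.nonzero(present)):
        net.add_edge(int(u), int(v))
    return net


def _distance_cdf(triple: ERTriple, max_hops: int) -> np.ndarray:
    """Annealed-BFS P(d(s,t) <= k) for k = 1..max_hops (z = 0 ensemble).

    Tracks reach probabilities of a generic non-source-node source (``a``)
    and a generic target (``b``); layer k's newly reached counts drive
    layer k+1 through independent-edge thinning.  k = 1 and k = 2 are
    exact under edge independence.
    """
    p, q = triple.p, triple.q
    nS, nT = triple.n_sources, triple.n_targets
    a_prev, b_prev = 0.0, 0.0
    a_cur, b_cur = p, q  # distance <= 1
    cdf = [b_cur]
    for _ in range(1, max_hops):
        # counts newly reached at the current deepest layer
        new_a = (nS - 1) * (a_cur - a_prev)
        new_b = (nT - 1) * (b_cur - b_prev)
        a_nxt = 1.0 - (1.0 - a_cur) * (1.0 - p) ** new_a
        b_nxt = 1.0 - (1.0 - b_cur) * (1.0 - q) ** new_a * (1.0 - p) ** new_b
        # s itself is already folded in through a_cur = p, b_cur = q
        a_prev, b_prev = a_cur, b_cur
        a_cur, b_cur = a_nxt, b_nxt
        cdf.append(b_cur)
        if b_cur > 1 - 1e-12:
            break
    return np.array(cdf)


def expected_efficiency(
    triple: ERTriple,
    penalty: float | None = None,
    rng: np.random.Generator | None = None,
    mc_graphs: int = 500,
    mc_pairs: int = 20,
) -> float:
    """Expected source-to-target shortest-path distance in the ensemble.

    For ``z = 0`` a hop-layer recursion is used (see module docstring);
    residual disconnection mass is charged at ``penalty`` (default ``2n``,
    matching evaluation).  For ``z > 0`` a Monte-Carlo fallback averages
    BFS distances over sampled graphs (``rng`` required).
    """
    if penalty is None:
        penalty = 2 * triple.n
    if triple.z > 0:
        if rng is None:
            raise ValueError("z > 0 requires a Generator for Monte-Carlo fallback")
        return _mc_efficiency(triple, penalty, rng, mc_graphs, mc_pairs)
    if triple.q >= 1.0:
        return 1.0
    cdf = _distance_cdf(triple, max_hops=triple.n)
    pmf = np.diff(np.concatenate([[0.0], cdf]))
    hops = np.arange(1, len(cdf) + 1)
    reach = cdf[-1]
    return float((pmf * hops).sum() + (1.0 - reach) * penalty)


def _mc_efficiency(
    triple: ERTriple,
    penalty: float,
    rng: np.random.Generator,
    graphs: int,
    pairs: int,
) -> float:
    from .graph_core import bfs_distance

    nS = triple.n_sources
    total = 0.0
    count = 0
    for _ in range(graphs):
        net = sample_er(triple, rng)
        for _ in range(pairs):
            s = int(rng.integers(0, nS))
            t = int(rng.integers(nS, triple.n))
            d = bfs_distance(net, s, t)
            total += penalty if d is None else d
            count += 1
    return total / count


def predict_pq(
    schedule: PruneSchedule,
    n: int,
    B: int,
    p_pairs: int,
    max_usage: int = 120,
) -> ERTriple:
    """Mean-field prediction of the final (p, q, z) class densities.

    Starting from the clique (all densities 1) under the 2-patch
    distribution, the recurrence tracks, for every edge class, the full
    distribution of cumulative usage over integer levels.  Each interval:

    1. computes the expected per-edge usage increment of every class from
       the current class densities (a routed pair crosses exactly one
       source-to-target edge and ``d - 1`` within-half edges; never a
       target-to-source edge while shorter routes exist),
    2. convolves each class's usage histogram with a Poisson increment of
       that mean, and
    3. removes the schedule's edge quota from the lowest usage level
       upward, pro-rata across classes within a level (mirroring
       lowest-usage-first pruning with random tie-breaking).

    Tracking the histogram rather than a single rate preserves survivor
    bias: edges that survive an early cut sit in the upper usage tail and
    keep attracting traffic, which is what differentiates schedules that
    cut early from those that cut late.  Returns the surviving densities
    as an :class:`ERTriple`.
    """
    nS = (n + 1) // 2
    nT = n - nS
    E0 = n * (n - 1)
    if schedule.E0 != E0 or schedule.B != B:
        raise ValueError("schedule was solved for a different (E0, B)")
    # class sizes: within-half (p), source->target (q), target->source (z)
    sizes = {
        "p": nS * (nS - 1) + nT * (nT - 1),
        "q": nS * nT,
        "z": nT * nS,
    }
    # usage histograms: hist[c][k] = expected # class-c edges at usage k
    hist = {
        c: np.concatenate([[float(sizes[c])], np.zeros(max_usage)])
        for c in sizes
    }
    removals = schedule.removal_counts()
    pairs_per_block = p_pairs / schedule.K

    for i in range(schedule.K):
        m = {c: float(hist[c].sum()) for c in sizes}
        triple = ERTriple(
            p=min(m["p"] / sizes["p"], 1.0),
            q=min(m["q"] / sizes["q"], 1.0),
            z=0.0,
            n=n,
        )
        cdf = _distance_cdf(triple, max_hops=min(n, 30))
        pmf = np.diff(np.concatenate([[0.0], cdf]))
        reach = float(cdf[-1])
        e_len = float((pmf * np.arange(1, len(cdf) + 1)).sum())
        delta = {
            "p": pairs_per_block * max(e_len - reach, 0.0) / max(m["p"], 1.0),
            "q": pairs_per_block * reach / max(m["q"], 1.0),
            "z": 0.0,
        }
        for c in sizes:
            if delta[c] > 0:
                inc = poisson.pmf(np.arange(max_usage + 1), delta[c])
                hist[c] = np.convolve(hist[c], inc)[: max_usage + 1]
        # remove the interval's quota from the lowest usage level upward
        remaining = float(removals[i])
        for level in range(max_usage + 1):
            if remaining <= 1e-9:
                break
            avail = sum(hist[c][level] for c in sizes)
            if avail <= 0:
                continue
            take = min(avail, remaining)
            for c in sizes:
                hist[c][level] -= hist[c][level] * take / avail
            remaining -= take

    clip = lambda x: float(min(max(x, 0.0), 1.0))
    return ERTriple(
        p=clip(hist["p"].sum() / sizes["p"]),
        q=clip(hist["q"].sum() / sizes["q"]),
        z=clip(hist["z"].sum() / sizes["z"]),
        n=n,
    )
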
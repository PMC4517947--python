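"""Source-target pair distributions.

During training a network observes an online stream of (source, target)
pairs drawn from an activity distribution D.  The patch-structured kinds
below model directional signalling between populations (a source half and a
target half of the node set, optionally with selectively more active
subsets, unbalanced sizes, or two parallel patches one of which is silenced
mid-development, mimicking monocular deprivation).  The ``empirical`` kind
wraps observed traffic counts, e.g. an origin-destination passenger matrix,
where a node can be both source and target.

Partitions are deterministic given (kind, n): sources occupy the lowest
labels and targets the highest, so identical configurations always mean the
same node sets.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np

KINDS = (
    "two_patch",
    "two_s_patch",
    "two_patch_unbalanced",
    "four_patch",
    "four_patch_hw",
    "empirical",
)

__all__ = [
    "PairDistribution",
    "make_distribution",
    "sample_pairs",
    "read_traffic_csv",
    "TrafficFormatError",
]


class TrafficFormatError(ValueError):
    """Malformed traffic-matrix CSV; message names the offending row."""


@dataclass
class PairDistribution:
    """A sampler of (source, target) node pairs.

    Attributes
    ----------
    kind : str
        One of :data:`KINDS`.
    n : int
        Node count of the networks this distribution drives.
    sources, targets : ndarray
        The full source and target label sets (may overlap for ``empirical``).
    params : dict
        Kind-specific parameters (e.g. mix probability ``x``, selective-set
        fraction, ``shutoff_fraction`` for the Hubel-Wiesel variant).
    """

    kind: str
    n: int
    sources: np.ndarray
    targets: np.ndarray
    params: dict = field(default_factory=dict)
    # patch sub-structure, populated per kind
    groups: dict = field(default_factory=dict)
    # empirical support
    pairs: np.ndarray | None = None
    probs: np.ndarray | None = None
    labels: list[str] | None = None

    def pair_probability(self, s: int, t: int) -> float:
        """Analytic probability of drawing the ordered pair (s, t)."""
        k = self.kind
        if k == "empirical":
            for (u, v), pr in zip(self.pairs, self.probs):
                if (u, v) == (s, t):
                    return float(pr)
            return 0.0
        if k in ("four_patch", "four_patch_hw"):
            prob = 0.0
            for i in (1, 2):
                Si, Ti = self.groups[f"S{i}"], self.groups[f"T{i}"]
                if s in Si and t in Ti:
                    prob += 0.5 / (len(Si) * len(Ti))
            return prob
        S, T = self.groups["S"], self.groups["T"]
        if k in ("two_patch", "two_patch_unbalanced"):
            in_support = s in S and t in T
            return 1.0 / (len(S) * len(T)) if in_support else 0.0
        if k == "two_s_patch":
            x = self.params["x"]
            Ss, Ts = self.groups["S_sel"], self.groups["T_sel"]
            prob = 0.0
            if s in S and t in T:
                prob += x / (len(S) * len(T))
            if s in Ss and t in Ts:
                prob += (1.0 - x) / (len(Ss) * len(Ts))
            return prob
        raise ValueError(f"unknown kind {k!r}")


def _split(lo: int, hi: int) -> np.ndarray:
    return np.arange(lo, hi)


def make_distribution(
    kind: str,
    n: int,
    params: dict | None = None,
    rng: np.random.Generator | None = None,
) -> PairDistribution:
    """Construct a pair distribution of the given kind over ``n`` nodes.

    Kinds
    -----
    two_patch
        Sources = lowest ceil(n/2) labels, targets = the rest; pairs uniform.
    two_s_patch
        As two_patch, but with probability ``1 - x`` the pair is drawn from
        selective subsets comprising a fraction (default 10%) of each side;
        default ``x = 0.5``.
    two_patch_unbalanced
        Three times as many targets as sources (|S| = n // 4).
    four_patch
        Two disjoint (S_i, T_i) patches, each pair drawn within a uniformly
        chosen patch.
    four_patch_hw
        As four_patch, but after ``shutoff_fraction`` of a training stream
        the second source set is silenced and its targets are recruited by
        the first source set (pairs S1 -> T1 u T2).
    empirical
        Categorical over explicit pairs proportional to counts
        (see :func:`read_traffic_csv`).
    """
    params = dict(params or {})
    if kind not in KINDS:
        raise ValueError(f"unknown distribution kind {kind!r}")
    if kind == "empirical":
        raise ValueError("build empirical distributions via read_traffic_csv")

    if kind in ("two_patch", "two_s_patch"):
        if n < 2:
            raise ValueError(f"{kind} needs n >= 2, got {n}")
        n_src = (n + 1) // 2
        S, T = _split(0, n_src), _split(n_src, n)
        groups = {"S": S, "T": T}
        if kind == "two_s_patch":
            params.setdefault("x", 0.5)
            params.setdefault("selective_fraction", 0.10)
            f = params["selective_fraction"]
            k_s = max(1, int(round(f * len(S))))
            k_t = max(1, int(round(f * len(T))))
            groups["S_sel"] = S[:k_s]
            groups["T_sel"] = T[:k_t]
        return PairDistribution(kind, n, S, T, params, groups)

    if kind == "two_patch_unbalanced":
        n_src = n // 4
        if n_src < 1 or n - n_src < 3:
            raise ValueError(f"two_patch_unbalanced infeasible for n={n}")
        S, T = _split(0, n_src), _split(n_src, n_src * 4)
        if len(T) != 3 * len(S):  # trim ragged n so |T| = 3|S| exactly
            T = _split(n_src, n)
        groups = {"S": S, "T": T}
        return PairDistribution(kind, n, S, T, params, groups)

    if kind in ("four_patch", "four_patch_hw"):
        if n < 4:
            raise ValueError(f"{kind} needs n >= 4, got {n}")
        q1, q2, q3 = n // 4, n // 2, 3 * n // 4
        groups = {
            "S1": _split(0, q1),
            "S2": _split(q1, q2),
            "T1": _split(q2, q3),
            "T2": _split(q3, n),
        }
        if kind == "four_patch_hw":
            params.setdefault("shutoff_fraction", 0.5)
        S = np.concatenate([groups["S1"], groups["S2"]])
        T = np.concatenate([groups["T1"], groups["T2"]])
        return PairDistribution(kind, n, S, T, params, groups)

    raise AssertionError("unreachable")


def _uniform_pairs(
    A: np.ndarray, B: np.ndarray, count: int, rng: np.random.Generator
) -> np.ndarray:
    s = A[rng.integers(0, len(A), size=count)]
    t = B[rng.integers(0, len(B), size=count)]
    return np.column_stack([s, t])


def sample_pairs(
    dist: PairDistribution, p: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw an ordered stream of ``p`` i.i.d. pairs as an ``(p, 2)`` array.

    The same pair may recur.  For ``four_patch_hw`` the mixture changes at
    the shutoff point: afterwards the second source set is never drawn and
    patch-1 sources pair uniformly with targets from both patches.
    """
    if p < 1:
        raise ValueError(f"stream length must be >= 1, got {p}")
    k = dist.kind
    g = dist.groups

    if k == "empirical":
        idx = rng.choice(len(dist.probs), size=p, p=dist.probs)
        return dist.pairs[idx].copy()

    if k in ("two_patch", "two_patch_unbalanced"):
        return _uniform_pairs(g["S"], g["T"], p, rng)

    if k == "two_s_patch":
        x = dist.params["x"]
        broad = rng.random(p) < x
        out = np.empty((p, 2), dtype=np.int64)
        nb = int(broad.sum())
        out[broad] = _uniform_pairs(g["S"], g["T"], nb, rng)
        out[~broad] = _uniform_pairs(g["S_sel"], g["T_sel"], p - nb, rng)
        return out

    if k in ("four_patch", "four_patch_hw"):
        shutoff = p + 1
        if k == "four_patch_hw":
            shutoff = int(np.floor(dist.params["shutoff_fraction"] * p))
        patch = rng.integers(1, 3, size=p)
        out = np.empty((p, 2), dtype=np.int64)
        T_all = np.concatenate([g["T1"], g["T2"]])
        for i in range(p):
            if i >= shutoff:  # second sources silenced, targets recruited
                s = g["S1"][rng.integers(0, len(g["S1"]))]
                t = T_all[rng.integers(0, len(T_all))]
            else:
                j = patch[i]
                s = g[f"S{j}"][rng.integers(0, len(g[f"S{j}"]))]
                t = g[f"T{j}"][rng.integers(0, len(g[f"T{j}"]))]
            out[i] = (s, t)
        return out

    raise ValueError(f"unknown kind {k!r}")


def read_traffic_csv(text: str) -> PairDistribution:
    """Parse a ``source,target,count`` CSV into an empirical distribution.

    City names (arbitrary strings) are mapped to dense integer labels in
    sorted order; the mapping is available as ``dist.labels`` (index =
    node label).  A node may appear as both source and target.  Zero or
    negative counts and self-pairs are format errors.
    """
    reader = csv.reader(io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        raise TrafficFormatError("empty traffic CSV") from None
    if [h.strip().lower() for h in header] != ["source", "target", "count"]:
        raise TrafficFormatError(
            f"row 1: expected header 'source,target,count', got {header!r}"
        )
    rows: list[tuple[str, str, int]] = []
    for rowno, row in enumerate(reader, start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != 3:
            raise TrafficFormatError(f"row {rowno}: expected 3 fields, got {row!r}")
        src, dst, cnt_s = (f.strip() for f in row)
        try:
            cnt = int(cnt_s)
        except ValueError:
            raise TrafficFormatError(
                f"row {rowno}: non-integer count {cnt_s!r}"
            ) from None
        if cnt <= 0:
            raise TrafficFormatError(f"row {rowno}: count must be positive, got {cnt}")
        if src == dst:
            raise TrafficFormatError(f"row {rowno}: self-pair {src!r}")
        rows.append((src, dst, cnt))
    if not rows:
        raise TrafficFormatError("traffic CSV contains no data rows")

    labels = sorted({name for r in rows for name in r[:2]})
    index = {name: i for i, name in enumerate(labels)}
    seen: set[tuple[int, int]] = set()
    pairs, counts = [], []
    for src, dst, cnt in rows:
        key = (index[src], index[dst])
        if key in seen:
            raise TrafficFormatError(f"duplicate pair {src!r} -> {dst!r}")
        seen.add(key)
        pairs.append(key)
        counts.append(cnt)
    pairs_arr = np.array(pairs, dtype=np.int64)
    probs = np.array(counts, dtype=float)
    probs /= probs.sum()
    nodes = np.arange(len(labels))
    return PairDistribution(
        kind="empirical",
        n=len(labels),
        sources=np.unique(pairs_arr[:, 0]),
        targets=np.unique(pairs_arr[:, 1]),
        params={},
        groups={"nodes": nodes},
        pairs=pairs_arr,
        probs=probs,
        labels=labels,
    )
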
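# Methods

This note records the model, the parameter choices that matter, the
numerical decisions, and what the synthetic test-bed does and does not
establish about real systems.

## The construction problem

A network of `n` nodes (labels `0..n-1`) observes an online stream of
`p` source–target pairs drawn i.i.d. from an activity distribution `D` and
must end construction holding at most `B` directed, unweighted edges.
Quality is scored on a fresh stream from the same `D`: mean shortest-path
hops (efficiency, lower better), mean count of routes at most one hop
longer than the shortest (robustness, higher better), disconnected-pair
count, and the cumulative number of edges maintained during construction
(energy).  Pair streams are online and repeatable — the same pair may
recur — and train/test streams are independent, so a good network must
generalize the activity structure rather than memorize observed pairs.

## Builders

**Pruning.**  Start from the complete directed graph.  Route each training
pair along a shortest path; every edge on the path gains one usage count
(cumulative across the whole run — counters are never reset).  After each
of `K = 10` intervals (one per tenth of the stream), remove the schedule's
quota of lowest-usage edges, ties uniform at random.  Unroutable training
pairs are skipped and contribute nothing.

*Routing-tie policy.*  When several shortest paths exist, the builder
breaks ties with a per-build random node-priority order mixed with the
destination label — every (node, destination) has a stable next hop, as in
a distributed routing table.  This consistency is load-bearing: it makes
traffic revisit the same relay edges, so usage concentrates on a stable
backbone that survives elimination.  Replacing it with per-query uniform
sampling over shortest paths (available as `route_policy="uniform"`)
spreads usage so thinly that sparse pruned networks fragment (measured at
n=200, B=2n: ~7% of test pairs disconnected versus ~2% under the table
policy) and the pruning advantage over growing disappears.  The library's
standalone `shortest_path` defaults to exact-uniform sampling (via BFS
path counts), which is the right neutral choice for measurement; only the
builders pass a priority.

**Flow.**  A more biologically plausible activity model requiring no
global shortest-path computation: per training pair, every edge
independently fails with probability 0.65 (synaptic transmission failure);
every surviving edge that lies on a surviving source-to-target route —
tail reachable from the source, head co-reaching the target, after
removing in-edges of the source and out-edges of the target — is rewarded
once per episode.  Rewarding per-episode membership rather than
per-path keeps the update order-independent and avoids enumerating
exponentially many paths.  Elimination is identical to the pruning
builder.

**Growing.**  The engineering baseline: a uniformly random spanning tree
(random Prüfer sequence), installed as `2(n-1)` arcs, guarantees every
pair a route.  Each routed training pair adds shortcut demand to every
ordered node pair at distance 2 along its route; after each block the
highest-demand absent arcs are installed in equal installments until the
budget is reached.

**No-learning.**  `B` directed edges uniform without replacement.

## Schedules

Per-interval removal fractions `r_1..r_K` of *currently existing* edges.
Constant solves `(1-r)^K E0 = B` in closed form.  Decreasing/increasing
use a geometric family `r_i = c·γ^(i-1)` (defaults γ=0.5 and γ=2) with `c`
solved by bisection for budget exactness; `γ ↦ 1/γ` exactly reverses the
fraction sequence.  Ending removes everything in one final cut.  Integer
rounding removes `round(r_i · current)` per interval with the final
interval forced to land exactly on `B`.  At very sparse budgets
(`B/E0 ≈ 0.01`) the geometric decreasing schedule is extreme — the first
interval removes >90% of the clique — which widens the gap to the
increasing schedule and narrows the gap to constant relative to gentler
decreasing shapes.

## Evaluation choices

* **Disconnection penalty.**  `efficiency()` charges a fixed distance for
  unreachable pairs; the standalone default is `2n` (safely above any
  path length).  The experiment driver instead uses a fixed constant of
  25 hops: an order of magnitude above typical routable distances at the
  scales studied, but small enough that baselines with an irreducible
  disconnected fraction (a random mean-out-degree-2 digraph never routes
  roughly a third of its pairs) are compared on the same scale as their
  routable distances instead of being annihilated by the penalty term.
  With a penalty on the order of `n`, the comparison degenerates into a
  pure disconnection count.
* **Robustness counting.**  The iterative search finds a shortest path,
  counts it if within one extra hop of the original distance, removes its
  interior nodes (for a direct edge, the edge itself), and repeats.  By
  default the primary path is included, so a connected pair scores ≥ 1;
  `count_primary=False` counts surviving alternatives only.  Ratios
  between algorithms are only meaningful in the alternatives-only
  convention (the +1 offset swamps small counts), which is what the
  comparison driver reports for fold ratios.  The airline analysis scores
  alternatives with zero extra hops (same-length routes), the natural
  reading for transport redundancy.
* Path selection inside robustness is deterministic (lexicographically
  smallest shortest path) so reports are reproducible without a seed.

## Motif analysis

Exact 16-class triad census (networkx's Batagelj–Mrvar implementation),
with per-class Z-scores and one-sided empirical p-values against an
ensemble of randomized networks.  Two nulls: degree-preserving two-edge
swaps (100·|E| attempts per sample; the field-standard conditioning) and
uniform `G(n, m)` at matched edge count.  The feed-forward signal in
selectively-active two-patch networks lives in the *degree structure*
created by the active subsets, so it is visible against the same-density
`G(n, m)` null (Z ≈ 5–7 at n=200) and invisible once degrees are
conditioned away; under the uniform two-patch distribution the
feed-forward class is unremarkable in both nulls.  Sparse-triad (021)
classes are inflated under `G(n, m)` whenever hubs are present — a
degree artifact, not circuit structure — so "nothing over-represented"
claims are checked under the swap null.

## Random-graph theory

Final two-patch networks are approximated by a directed ensemble with
within-half edge probability `p`, source→target probability `q`, and
target→source probability `z`.  Because a source-to-target route with
`z = 0` crosses exactly one `q`-edge and `d-1` `p`-edges, routing traffic
splits cleanly between the classes.

`expected_efficiency` computes the source→target distance distribution by
an annealed hop-layer recursion (exact at 1 and 2 hops under edge
independence) and charges residual unreached mass at the evaluation
penalty.  It is accurate where most pairs route within ~3 hops
(validated within Monte-Carlo error over `p, q ∈ [0.1, 0.5]` at n=200);
near the percolation threshold it overestimates the disconnected fraction
(e.g. by ~0.3 hops of penalty mass at `p=0.05, q=0.02`, n=200) — a known
limitation.

`predict_pq` tracks, per class, the full histogram of cumulative edge
usage: each interval adds a Poisson usage increment with the class's
expected per-edge traffic, then removes the schedule's quota from the
lowest usage level upward (pro-rata within a level, mirroring random
tie-breaking).  The histogram preserves survivor bias across intervals.
The recurrence is a calibrated surrogate validated against the simulator,
not a closed form.  It reproduces the dominant structure — late-cutting
schedules (ending, increasing) end with `q/p` far above early-cutting
ones, and `z → 0` at sparse budgets — but at desk scale it orders the two
early-cutting schedules (constant, decreasing) opposite to the simulator,
whose routing-table hub concentration makes within-class usage far more
overdispersed than Poisson.  Agreement is therefore asserted as rank
correlation with that bottom-pair swap tolerated.

## Pruning-rate estimation

Synapse-density series (sample, postnatal day, density) are fitted with a
cubic smoothing spline through per-age means, smoothing chosen by
generalized cross-validation (exact interpolation available; linear
fallback below four distinct ages; no extrapolation).  The window
P19–P39 is split into `k` equal intervals and each interval's loss is
expressed as a percentage of the density at the window start, so results
are invariant to density units.  Uncertainty comes from leave-one-out
refits — drop one sample, or one canonical 2-day time-point bin (P14;
P17; P19; P21+22; P23+24; P26; P28; P30; P32+33; P34+36; P38; P40) — with
an unpaired t-test between successive intervals' fold values.  Two
caveats, both visible in the tests: folds differ by a single sample, so
the fold t-test is anti-conservative (it can flag 1–2-point wiggles on
linear-decay data whose intervals are equal in truth — null checks should
read the interval gap, not the p-value); and the smoothing spline rounds
sharp kinks, biasing interval percentages by ~1–3 points when the true
curve is piecewise linear.  The packaged reference table (per-time-point
mean densities, mouse barrel cortex, P14–P40) yields a first-interval
loss several times the second-interval loss — the decreasing-rate
signature — under every fold scheme.

The 3-D stereological adjustment multiplies areal densities by
`T/(T + D)` (section thickness, object diameter), the standard
thickness correction; with an age-independent diameter it cancels out of
all percentage-based results.

## Synthetic data

The density generator emulates per-animal noisy measurements on the
canonical P14–P40 time-points around an exponential, linear, or
piecewise-linear decay (defaults: peak 3.3 at P19 to plateau 1.6 at P40,
matching the packaged reference scale; Gaussian noise SD 0.25 truncated at
zero; 3 animals per time-point).  The traffic generator emits Zipf-ranked
passenger counts over sampled ordered city pairs (defaults: 122 cities,
top 1000 pairs), matching the heavy-tailed character of real
origin–destination matrices.  Neither generator models measurement
artifacts (staining variability, classifier bias) or temporal correlation
within animals, so passing tests establish correctness of the estimators
under the stated generative model, not robustness to those artifacts.

## Study conditions and problem sizes

The default comparison grid is the sparse regime where schedule choice
matters most: `B = 2n`, `K = 10`, training volume `p = 10n`, equal test
volume, 3 replicates per cell, with a per-cell seed derived from the base
seed and the cell name so grids are extensible without perturbing
existing cells.  Simulations in the tests and the acceptance script run
at `n = 200`; the qualitative orderings (pruning beats no-learning beats
growing on efficiency; decreasing beats constant beats increasing;
growing's zero disconnections; the energy ordering) are stable across
seeds at this size, while fold magnitudes grow with `n` (the
growing-to-pruning efficiency fold rises from ~2.2 at n=200 toward ~3.4
at n=600 as tree routes lengthen).  Under the flow model at small n only
the decreasing-versus-constant gap is resolvable; the constant-versus-
increasing ordering is within run-to-run noise.

## Known limitations

* No synaptic weights, spike timing, inhibition, or multi-neuron
  coincidence — construction is purely graph-theoretic.
* The geometric schedule family is one interpretable choice among many
  monotone shapes; conclusions about "decreasing vs increasing" are tied
  to mirror-symmetric pairs (γ, 1/γ).
* The mean-field recurrence and the annealed efficiency recursion are
  surrogates validated against simulation in stated regimes, not exact
  results.
* Desk-scale runs under-resolve effects that need `n ≳ 10³` (full fold
  magnitudes, flow-model orderings).
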
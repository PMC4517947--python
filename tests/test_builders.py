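"""Construction algorithms: pruning, flow, growing, no-learning."""

import inspect

import networkx as nx
import numpy as np
import pytest

from prunenet.builders import (
    _flow_reward_edges,
    _random_spanning_tree,
    build_by_flow,
    build_by_growing,
    build_by_pruning,
    build_no_learning,
    route_and_record,
)
from prunenet.distributions import make_distribution, read_traffic_csv
from prunenet.evaluation import unroutable
from prunenet.graph_core import UsageTable, make_clique
from prunenet.schedules import edges_after, make_schedule

from conftest import random_digraph


def two_patch(n):
    return make_distribution("two_patch", n)


class TestUsageTracking:
    def test_routed_pair_increments_usage_by_path_length(self, rng):
        # conservation: total usage increment per pair equals its hop count
        for _ in range(20):
            net = random_digraph(8, 30, rng)
            usage = UsageTable()
            s, t = 0, 7
            hops = route_and_record(net, usage, s, t, rng)
            if hops is None:
                assert not usage
            else:
                assert sum(usage.values()) == hops

    def test_clique_first_interval_usage_is_direct_pair_multiplicity(self, rng):
        net = make_clique(6)
        usage = UsageTable()
        pairs = [(0, 3), (0, 3), (1, 4), (0, 3)]
        for s, t in pairs:
            route_and_record(net, usage, s, t, rng)
        assert usage[(0, 3)] == 3 and usage[(1, 4)] == 1
        assert sum(usage.values()) == 4


class TestPruningBuilder:
    def test_high_usage_direct_edges_survive_single_cut(self, rng):
        # trained only on three pairs, budget 3: exactly those direct edges
        csv = "source,target,count\nn0,n2,5\nn1,n3,5\nn0,n3,5\n"
        dist = read_traffic_csv(csv)
        sched = make_schedule("ending", 12, 3, 1)
        trace = build_by_pruning(dist, 4, 3, sched, 300, rng)
        assert set(trace.network.edges()) == {(0, 2), (1, 3), (0, 3)}

    def test_edge_trajectory_matches_schedule_exactly(self, rng):
        n, B = 30, 60
        sched = make_schedule("constant", n * (n - 1), B, 10)
        trace = build_by_pruning(two_patch(n), n, B, sched, 300, rng)
        assert trace.edge_counts == edges_after(sched)
        assert trace.network.num_edges == B

    def test_minimal_stream_one_pair_per_interval(self, rng):
        n, B = 10, 20
        sched = make_schedule("constant", n * (n - 1), B, 10)
        trace = build_by_pruning(two_patch(n), n, B, sched, 10, rng)
        assert trace.network.num_edges == B

    def test_identical_seeds_reproduce_identical_traces(self):
        n, B = 24, 48
        sched = make_schedule("decreasing", n * (n - 1), B, 10)
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            tr = build_by_pruning(two_patch(n), n, B, sched, 240, rng)
            runs.append((sorted(tr.network.edges()), tr.to_dict()))
        assert runs[0] == runs[1]

    def test_empty_stream_rejected(self, rng):
        sched = make_schedule("constant", 90, 10, 10)
        with pytest.raises(ValueError, match="non-empty"):
            build_by_pruning(two_patch(10), 10, 10, sched, 0, rng)


class TestFlowBuilder:
    def test_default_failure_probability(self):
        assert (
            inspect.signature(build_by_flow).parameters["fail_prob"].default
            == 0.65
        )

    @pytest.mark.parametrize("n", [4, 5])
    def test_lossless_clique_rewards_match_simple_path_oracle(self, n):
        # with no failures every edge on >= 1 simple s->t path is rewarded
        net = make_clique(n)
        edges = net.edges()
        alive = np.ones(len(edges), dtype=bool)
        s, t = 0, n - 1
        rewarded = {edges[i] for i in _flow_reward_edges(edges, alive, n, s, t)}
        g = nx.DiGraph(edges)
        oracle = set()
        for path in nx.all_simple_paths(g, s, t):
            oracle.update(zip(path, path[1:]))
        assert rewarded == oracle
        assert not any(v == s or u == t for u, v in rewarded)

    def test_total_signal_loss_rewards_nothing(self, rng):
        n, B = 10, 20
        sched = make_schedule("ending", n * (n - 1), B, 1)
        trace = build_by_flow(
            two_patch(n), n, B, sched, 5, rng, fail_prob=0.999
        )
        assert trace.intervals[-1].usage_total == 0

    def test_builds_to_budget_under_default_loss(self, rng):
        n, B = 16, 40
        sched = make_schedule("constant", n * (n - 1), B, 5)
        trace = build_by_flow(two_patch(n), n, B, sched, 80, rng)
        assert trace.network.num_edges == B


class TestGrowingBuilder:
    def test_tree_backbone_makes_every_pair_routable(self, rng):
        n = 30
        trace = build_by_growing(two_patch(n), n, 2 * (n - 1), 100, rng)
        assert trace.network.num_edges == 2 * (n - 1)
        from prunenet.distributions import sample_pairs

        test = sample_pairs(two_patch(n), 300, rng)
        assert unroutable(trace.network, test) == 0

    def test_repeated_route_demands_distance_two_shortcuts(self, rng):
        # path tree 0-1-2-3, traffic only 0 -> 3: the two extra arcs must
        # shortcut the observed route, i.e. come from {(0,2), (1,3)}
        from prunenet.distributions import PairDistribution

        dist = PairDistribution(
            kind="empirical", n=4,
            sources=np.array([0]), targets=np.array([3]),
            pairs=np.array([[0, 3]]), probs=np.array([1.0]),
        )
        trace = build_by_growing(
            dist, 4, 2 * 3 + 2, 40, rng, K=1, tree=[(0, 1), (1, 2), (2, 3)]
        )
        added = set(trace.network.edges()) - {
            (0, 1), (1, 0), (1, 2), (2, 1), (2, 3), (3, 2)
        }
        assert added and added <= {(0, 2), (1, 3)}

    def test_infeasible_budget_rejected(self, rng):
        with pytest.raises(ValueError, match="B >= 2"):
            build_by_growing(two_patch(10), 10, 17, 50, rng)

    def test_pruefer_tree_is_a_spanning_tree(self, rng):
        for n in (2, 3, 8, 40):
            edges = _random_spanning_tree(n, rng)
            g = nx.Graph(edges)
            g.add_nodes_from(range(n))
            assert g.number_of_edges() == n - 1 and nx.is_connected(g)


class TestNoLearning:
    def test_full_budget_recovers_clique(self, rng):
        assert set(build_no_learning(6, 30, rng).network.edges()) == set(
            make_clique(6).edges()
        )

    def test_single_edge_choice_is_uniform(self):
        picks = [
            build_no_learning(2, 1, np.random.default_rng(seed))
            .network.edges()[0]
            for seed in range(1000)
        ]
        frac01 = sum(e == (0, 1) for e in picks) / 1000
        assert 0.45 <= frac01 <= 0.55

    def test_quarter_of_random_edges_point_target_to_source(self, rng):
        # under a two-patch reading of the node set, ~25% of uniformly
        # random edges run from the target half back to the source half
        n, B = 40, 1000
        fracs = []
        for _ in range(5):
            net = build_no_learning(n, B, rng).network
            back = sum(1 for u, v in net.edges() if u >= n // 2 > v)
            fracs.append(back / B)
        assert abs(np.mean(fracs) - 0.25) < 0.03
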
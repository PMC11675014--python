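"""Validation (alpha/beta/S), circleness, changepoints, average delay."""

import itertools

import networkx as nx
import numpy as np
import pytest

from neuromapper import (average_delay, circleness, detect_transitions,
                         validate)
from neuromapper.evaluation import STATE_ORDER, label_nodes
from neuromapper.partial_clustering import Cluster, ClusterSet
from neuromapper.shapegraph import build_shape_graph


def graph_from(member_lists, n_points):
    cs = ClusterSet(clusters=[Cluster(members=np.array(m, dtype=int), bin_id=i,
                                      method="test")
                              for i, m in enumerate(member_lists)],
                    n_points=n_points)
    return build_shape_graph(cs)


def cycle_graph_of_nodes(k, per_node=1):
    """k nodes in a cycle, consecutive nodes sharing one point."""
    members = []
    for i in range(k):
        members.append([i, (i + 1) % k])
    return graph_from(members, k)


class TestValidate:
    def test_single_node_graph_invalid(self):
        g = graph_from([list(range(10))], n_points=10)
        rep = validate(g, tr=1.0)
        assert rep.beta == 100.0
        assert rep.entropy == 0.0
        assert not rep.valid

    def test_cycle_entropy_matches_direct_count(self):
        # 10-node cycle: hop counts {1:10, 2:10, 3:10, 4:10, 5:5}
        g = cycle_graph_of_nodes(10)
        counts = np.array([10, 10, 10, 10, 5], dtype=float)
        p = counts / counts.sum()
        expected = -(p * np.log2(p)).sum()
        rep = validate(g, tr=1.0)
        assert rep.entropy == pytest.approx(expected)
        assert rep.entropy == pytest.approx(2.2810, abs=1e-4)
        assert rep.entropy >= 2

    def test_alpha_counts_long_span_nodes(self):
        # node 0 spans indices 0..50 (50 s at tr=1 > tau=11); node 1 spans 2
        g = graph_from([[0, 50], [1, 3]], n_points=51)
        rep = validate(g, tr=1.0, tau=11.0)
        assert rep.alpha == 50.0
        g2 = graph_from([[0, 50], [1, 40]], n_points=51)
        assert validate(g2, tr=1.0).alpha == 100.0

    def test_beta_largest_component_percentage(self):
        g = graph_from([[0, 1], [1, 2], [3, 4]], n_points=10)
        rep = validate(g, tr=1.0)
        assert rep.beta == pytest.approx(30.0)

    def test_zero_nodes_rejected(self):
        g = graph_from([], n_points=5)
        with pytest.raises(ValueError):
            validate(g, tr=1.0)

    def test_invariant_to_node_relabeling(self, rng):
        members = [rng.choice(40, size=5, replace=False) for _ in range(12)]
        g1 = graph_from(members, 40)
        g2 = graph_from(list(reversed(members)), 40)
        r1, r2 = validate(g1, tr=0.5), validate(g2, tr=0.5)
        assert r1.alpha == r2.alpha and r1.beta == r2.beta
        assert r1.entropy == pytest.approx(r2.entropy)

    def test_thresholds_conjunction(self):
        g = cycle_graph_of_nodes(10)
        rep = validate(g, tr=5.0)  # every node spans >= 1 index * 5 s < tau
        assert rep.valid == (rep.alpha >= 15 and rep.beta > 70 and rep.entropy >= 2)


def circleness_path_oracle(graph, labels):
    """Brute-force enumeration of simple paths with the interior-label
    constraint, on small graphs."""
    states = label_nodes(graph, labels)
    G = graph.to_networkx()
    ok = {}
    for interior, removed in (("transition-up", "transition-down"),
                              ("transition-down", "transition-up")):
        keep = [n for n in G if states[n] != removed]
        H = G.subgraph(keep)
        found = False
        lows = [n for n in H if states[n] == "stable-low"]
        highs = [n for n in H if states[n] == "stable-high"]
        for s in lows:
            for t in highs:
                for path in nx.all_simple_paths(H, s, t):
                    inner = path[1:-1]
                    if inner and all(states[n] == interior for n in inner):
                        found = True
                        break
                if found:
                    break
            if found:
                break
        ok[interior] = found
    return ok["transition-up"] and ok["transition-down"]


class TestCircleness:
    L, U, H, D = STATE_ORDER

    def labels_for(self, node_states, graph):
        """Per-point labels making each node majority-labeled as desired
        (nodes here have disjoint single points plus shared ones)."""
        labels = np.array(["x"] * graph.n_points, dtype=object)
        for node, state in zip(graph.nodes, node_states):
            for m in node["members"]:
                labels[m] = state
        return labels.astype(str)

    def test_four_node_cycle_passes(self):
        labels = np.array([self.L, self.U, self.H, self.D])
        g = graph_from([[0], [1], [2], [3]], 4)
        g.edges = {(0, 1), (1, 2), (2, 3), (0, 3)}
        assert circleness(g, labels) is True

    def test_missing_down_arc_fails(self):
        g = graph_from([[0], [1], [2]], 3)
        g.edges = {(0, 1), (1, 2)}
        labels = np.array([self.L, self.U, self.H])
        assert circleness(g, labels) is False

    def test_direct_edge_allowed_unless_strict(self):
        g = graph_from([[0], [1], [2], [3]], 4)
        g.edges = {(0, 1), (1, 2), (2, 3), (0, 3), (0, 2)}
        labels = np.array([self.L, self.U, self.H, self.D])
        assert circleness(g, labels) is True
        assert circleness(g, labels, strict=True) is False

    def test_all_transition_nodes_deleted_fails(self):
        g = graph_from([[0], [1]], 2)
        g.edges = {(0, 1)}
        labels = np.array([self.L, self.H])
        assert circleness(g, labels) is False

    def test_label_length_checked(self):
        g = graph_from([[0], [1]], 2)
        with pytest.raises(ValueError):
            circleness(g, np.array([self.L]))

    def test_matches_brute_force_path_oracle(self):
        states = list(STATE_ORDER)
        for trial in range(30):
            rng = np.random.default_rng(trial)
            k = int(rng.integers(4, 9))
            g = graph_from([[i] for i in range(k)], k)
            possible = list(itertools.combinations(range(k), 2))
            m = int(rng.integers(k - 1, len(possible) + 1))
            idx = rng.choice(len(possible), size=m, replace=False)
            g.edges = {possible[i] for i in idx}
            labels = np.array([states[i] for i in
                               rng.integers(0, 4, size=k)])
            assert circleness(g, labels) == circleness_path_oracle(g, labels)


def changepoint_oracle(y, n_change):
    """Exhaustive search over all changepoint combinations."""
    T = len(y)
    best, best_cost = None, np.inf
    for cps in itertools.combinations(range(1, T), n_change):
        bounds = [0, *cps, T]
        cost = sum(float(np.var(y[a:b]) * (b - a))
                   for a, b in zip(bounds[:-1], bounds[1:]))
        if cost < best_cost - 1e-12:
            best_cost, best = cost, list(cps)
    return best


class TestDetectTransitions:
    def test_single_clean_step(self):
        y = np.concatenate([np.zeros(50), np.ones(50)])
        assert detect_transitions(y, n_change=1) == [50.0]

    def test_two_clean_steps_match_exhaustive_search(self):
        rng = np.random.default_rng(0)
        y = np.concatenate([np.zeros(40), np.full(40, 1.0), np.full(40, 0.3)])
        y += rng.normal(0, 0.02, y.size)
        got = detect_transitions(y, n_change=2)
        want = changepoint_oracle(y, 2)
        assert got == [float(c) for c in want]

    def test_matches_oracle_on_random_series(self):
        for trial in range(10):
            rng = np.random.default_rng(trial)
            y = rng.standard_normal(30)
            for n_change in (1, 2):
                got = detect_transitions(y, n_change=n_change)
                want = changepoint_oracle(y, n_change)
                assert got == [float(c) for c in want]

    def test_noise_robustness_of_step_location(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = np.concatenate([np.zeros(50), np.ones(50)])
            y += rng.normal(0, 0.05, 100)
            cp = detect_transitions(y, n_change=1)[0]
            hits += abs(cp - 50) <= 2
        assert hits >= 95

    def test_times_scale_with_tr(self):
        y = np.concatenate([np.zeros(50), np.ones(50)])
        assert detect_transitions(y, n_change=1, tr=0.72) == [pytest.approx(36.0)]

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            detect_transitions(np.ones(20), n_change=1)

    def test_length_validation(self):
        with pytest.raises(ValueError):
            detect_transitions(np.arange(3.0), n_change=3)


class TestAverageDelay:
    def test_exact_match_zero(self):
        assert average_delay([10.0, 20.0], [10.0, 20.0]) == 0.0

    def test_common_shift(self):
        assert average_delay([13.0, 23.0], [10.0, 20.0]) == pytest.approx(3.0)

    def test_missed_transition_inflates(self):
        # nearest to 200 is 100 or 300: (0 + 100 + 0) / 3
        assert average_delay([100.0, 300.0], [100.0, 200.0, 300.0]) == \
            pytest.approx(100.0 / 3.0)

    def test_empty_extraction_is_infinite(self):
        assert average_delay([], [10.0]) == np.inf

    def test_invariant_under_joint_time_shift(self, rng):
        ex = sorted(rng.uniform(0, 100, 5).tolist())
        exp = sorted(rng.uniform(0, 100, 4).tolist())
        base = average_delay(ex, exp)
        shifted = average_delay([t + 37.5 for t in ex], [t + 37.5 for t in exp])
        assert shifted == pytest.approx(base)

    def test_empty_expected_rejected(self):
        with pytest.raises(ValueError):
            average_delay([1.0], [])
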
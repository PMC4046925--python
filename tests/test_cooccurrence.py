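import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from succession import cooccurrence_network as conet
from succession.synthetic_data import generate_environment_matrix
from succession.timecores import Timecore


def _env(matrix, labels=None):
    df = pd.DataFrame(
        matrix,
        index=[f"t{i}" for i in range(len(matrix))],
        columns=[f"s{j}" for j in range(len(matrix[0]))],
    )
    labs = labels or ["E1"] * df.shape[1]
    return conet.EnvironmentMatrix(df, pd.Series(labs, index=df.columns))


class TestEnvironmentMatrix:
    def test_dominant_environment_majority_rule(self):
        env = _env([[1, 1, 1, 0], [1, 0, 1, 0], [0, 1, 0, 1]],
                   labels=["A", "A", "B", "B"])
        dom = env.dominant_environments()
        assert dom["t0"] == "A"             # s0(A), s1(A), s2(B): 2/3 -> A
        assert dom["t1"] == "cosmopolitan"  # s0(A), s2(B): tie
        assert dom["t2"] == "cosmopolitan"  # s1(A), s3(B): tie

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            _env([[2, 0], [0, 1]])


class TestNullEnsemble:
    def test_elementary_checkerboard_swap(self):
        """A lone 2x2 checkerboard in one stratum can only move to its
        complement; marginals are conserved either way."""
        env = _env([[1, 0], [0, 1]])
        # every attempt finds the unique checkerboard, so the state toggles:
        # an odd number of attempts yields the complement, an even number
        # returns the original
        [M_odd] = conet.null_ensemble(env, 1, seed=0, burn_in=1, thinning=0)
        np.testing.assert_array_equal(M_odd, [[0, 1], [1, 0]])
        [M_even] = conet.null_ensemble(env, 1, seed=0, burn_in=2, thinning=0)
        np.testing.assert_array_equal(M_even, [[1, 0], [0, 1]])

    def test_marginals_conserved_on_every_draw(self):
        rng = np.random.default_rng(0)
        M0 = (rng.random((12, 30)) < 0.4).astype(int)
        M0[:, 0] = 1  # avoid empty columns for realism
        labels = ["A"] * 15 + ["B"] * 15
        env = _env(M0.tolist(), labels=labels)
        ens = conet.null_ensemble(env, 10, seed=1, burn_in=500, thinning=100)
        labs = np.array(labels)
        for M in ens:
            np.testing.assert_array_equal(M.sum(axis=1), M0.sum(axis=1))
            np.testing.assert_array_equal(M.sum(axis=0), M0.sum(axis=0))
            for e in ("A", "B"):  # per-stratum occurrence counts
                np.testing.assert_array_equal(
                    M[:, labs == e].sum(axis=1), M0[:, labs == e].sum(axis=1)
                )

    def test_frozen_configuration_unchanged(self):
        # no 2x2 checkerboard exists: nested structure
        env = _env([[1, 1], [1, 0]])
        ens = conet.null_ensemble(env, 5, seed=2, burn_in=100, thinning=50)
        for M in ens:
            np.testing.assert_array_equal(M, [[1, 1], [1, 0]])

    def test_small_stratum_warned(self, caplog):
        env = _env([[1, 0, 1], [0, 1, 1]], labels=["A", "A", "B"])
        with caplog.at_level("WARNING"):
            conet.null_ensemble(env, 1, seed=0, burn_in=10, thinning=0)
        assert any("B" in str(r.message) for r in caplog.records)


class TestScoreAssociations:
    def test_pair_at_null_mean_not_called(self):
        rng = np.random.default_rng(3)
        M = (rng.random((6, 40)) < 0.5).astype(int)
        env = _env(M.tolist())
        ens = conet.null_ensemble(env, 30, seed=0)
        net = conet.score_associations(env, ens, fpr_threshold=0.05)
        # any pair with z exactly 0 must not be an edge
        for a, b, d in net.graph.edges(data=True):
            assert abs(d["z"]) >= net.z_threshold

    def test_identical_occurrence_vectors_aggregate(self):
        rng = np.random.default_rng(5)
        M = (rng.random((10, 80)) < 0.25).astype(int)
        M[1] = M[0]  # duplicated sparse occurrence vector
        env = _env(M.tolist())
        ens = conet.null_ensemble(env, 50, seed=1)
        net = conet.score_associations(env, ens, fpr_threshold=0.05)
        assert net.graph.has_edge("t0", "t1")
        assert net.graph["t0"]["t1"]["sign"] == "aggregation"

    def test_null_matrix_false_positive_rate(self):
        """With independent taxa the fraction of called pairs stays at or
        below the configured false-positive bound (averaged over seeds)."""
        rates = []
        for seed in range(5):
            truth = generate_environment_matrix(
                15, 120, 2, affinity=0.0, seed=seed)
            env = conet.EnvironmentMatrix(truth.matrix, truth.labels)
            ens = conet.null_ensemble(env, 40, seed=seed)
            net = conet.score_associations(env, ens, fpr_threshold=0.05)
            n_pairs = 15 * 14 / 2
            rates.append(net.graph.number_of_edges() / n_pairs)
        assert np.mean(rates) <= 0.05 + 0.02

    def test_empty_ensemble_rejected(self):
        env = _env([[1, 0], [0, 1]])
        with pytest.raises(ValueError, match="ensemble"):
            conet.score_associations(env, [], 0.05)


class TestTimecoreSubnetwork:
    def _parent(self, edges):
        G = nx.Graph()
        for a, b, sign, z in edges:
            G.add_edge(a, b, sign=sign, z=z)
        return conet.AssociationNetwork(G, 2.0, 0.05)

    def test_first_appearance_is_max_of_entry_times(self):
        parent = self._parent([("x", "y", "aggregation", 3.0)])
        cores = [
            Timecore("I2", frozenset({"x"}), 9),
            Timecore("I4", frozenset({"x", "y"}), 13),
        ]
        sub = conet.extract_timecore_subnetwork(parent, cores)
        assert sub.graph["x"]["y"]["first_appearance"] == "I4"

    def test_never_coresident_pair_excluded(self):
        parent = self._parent([("x", "y", "aggregation", 3.0),
                               ("x", "z", "aggregation", 2.5)])
        cores = [Timecore("I1", frozenset({"x", "z"}), 13),
                 Timecore("I2", frozenset({"y"}), 9)]
        sub = conet.extract_timecore_subnetwork(parent, cores)
        assert not sub.graph.has_edge("x", "y")
        assert sub.graph.has_edge("x", "z")

    def test_matches_exhaustive_pair_scan(self):
        rng = np.random.default_rng(7)
        taxa = [f"t{i}" for i in range(12)]
        edges = []
        for a, b in itertools.combinations(taxa, 2):
            if rng.random() < 0.3:
                edges.append((a, b, "aggregation" if rng.random() < 0.7 else "segregation",
                              float(rng.normal(3, 0.5))))
        parent = self._parent(edges)
        tps = ["I1", "I2", "I3", "I4", "I5", "MB"]
        cores = [Timecore(tp, frozenset(t for t in taxa if rng.random() < 0.5), 13)
                 for tp in tps]
        sub = conet.extract_timecore_subnetwork(parent, cores)
        by_tp = {tc.timepoint: tc.features for tc in cores}
        infant = [tp for tp in tps if tp != "MB"]
        for a, b, _, _ in edges:
            expected_first = next(
                (tp for tp in infant if a in by_tp[tp] and b in by_tp[tp]), None)
            expected_mb = a in by_tp["MB"] and b in by_tp["MB"]
            if expected_first is None and not expected_mb:
                assert not sub.graph.has_edge(a, b)
            else:
                d = sub.graph[a][b]
                assert d["first_appearance"] == expected_first
                assert d["in_mb"] == expected_mb


class TestMotifs:
    def _net(self, agg_edges, seg_edges=()):
        G = nx.Graph()
        for a, b in agg_edges:
            G.add_edge(a, b, sign="aggregation", z=3.0)
        for a, b in seg_edges:
            G.add_edge(a, b, sign="segregation", z=-3.0)
        return conet.AssociationNetwork(G, 2.0, 0.05)

    def test_triangle(self):
        tri, cliques = conet.find_transitive_motifs(
            self._net([("a", "b"), ("b", "c"), ("a", "c")]))
        assert tri == [("a", "b", "c")]
        assert cliques == [("a", "b", "c")]

    def test_k4_counts(self):
        nodes = "abcd"
        edges = list(itertools.combinations(nodes, 2))
        tri, cliques = conet.find_transitive_motifs(self._net(edges))
        assert len(tri) == 4  # C(4,3)
        assert cliques == [("a", "b", "c", "d")]

    def test_star_has_no_triangles(self):
        tri, cliques = conet.find_transitive_motifs(
            self._net([("hub", x) for x in "abcd"]))
        assert tri == []
        assert cliques == []

    def test_segregations_excluded_from_motifs(self):
        tri, _ = conet.find_transitive_motifs(
            self._net([("a", "b"), ("b", "c")], seg_edges=[("a", "c")]))
        assert tri == []


def test_edge_list_round_trip(tmp_path):
    G = nx.Graph()
    G.add_edge("x", "y", sign="aggregation", z=3.2)
    G.add_edge("y", "z", sign="segregation", z=-2.8)
    net = conet.AssociationNetwork(G, 2.0, 0.05)
    path = tmp_path / "edges.tsv"
    conet.write_edge_list(net, path)
    back = conet.read_edge_list(path)
    assert set(back.graph.edges) == set(G.edges)
    assert back.graph["x"]["y"]["sign"] == "aggregation"


def test_planted_association_recovery():
    """Planted aggregations and segregations at high affinity are recovered
    with high sensitivity and no sign confusion."""
    truth = generate_environment_matrix(
        24, 220, 2, affinity=0.85,
        n_planted_aggregations=4, n_planted_segregations=2, seed=13)
    env = conet.EnvironmentMatrix(truth.matrix, truth.labels)
    ens = conet.null_ensemble(env, 50, seed=3)
    net = conet.score_associations(env, ens, fpr_threshold=0.05)
    hits = sum(net.graph.has_edge(a, b)
               and net.graph[a][b]["sign"] == "aggregation"
               for a, b in truth.aggregated_pairs)
    hits += sum(net.graph.has_edge(a, b)
                and net.graph[a][b]["sign"] == "segregation"
                for a, b in truth.segregated_pairs)
    assert hits >= 5  # >= 5 of 6 planted pairs
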
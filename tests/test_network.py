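"""Co-occurrence network construction, subgraph topology, complexity PCA, modules."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import micronet as mn
from graph_oracle import brute_metrics
from micronet.network import CooccurrenceNetwork, CorrelationScreen, TOPO_COLUMNS
from test_community import _counts


def _net_from_edges(edges, crop="maize"):
    g = nx.Graph()
    for u, v in edges:
        g.add_edge(u, v, rho=0.9, q=1e-5)
    return CooccurrenceNetwork(g, crop)


def _metrics_of(edges, nodes=None):
    net = _net_from_edges(edges)
    present = set(nodes) if nodes else set(net.nodes)
    return mn.sample_subgraph_metrics(net, present)


class TestFilterTaxa:
    def test_rare_taxon_below_001_percent_is_removed(self):
        mat = np.zeros((2, 2), dtype=int)
        mat[0] = [999_999, 1]  # 1 read of 1,000,000 = 0.0001%
        mat[1] = [0, 0]
        mat[1, 0] = 1  # keep row sums positive
        out = mn.filter_taxa(_counts(mat))
        assert out.taxa_ids == ["T0"]

    def test_taxon_at_exactly_the_threshold_is_retained(self):
        mat = np.array([[9_999, 1]])  # threshold = 1 count; boundary kept
        out = mn.filter_taxa(_counts(mat))
        assert out.taxa_ids == ["T0", "T1"]

    def test_toy_table_hand_check(self):
        # grand total 20,000 -> threshold 2 counts; the last taxon (1) drops
        mat = np.array([[10_000, 8_000, 1_996, 3, 1]])
        out = mn.filter_taxa(_counts(mat))
        assert out.taxa_ids == ["T0", "T1", "T2", "T3"]

    def test_empty_result_errors(self):
        with pytest.raises(ValueError):
            mn.filter_taxa(_counts([[1, 1]]), min_fraction=10.0)


class TestCorrelationScreen:
    def test_monotone_pair_has_rho_one(self):
        mat = np.array([[1, 2], [2, 4], [3, 8], [4, 16], [5, 17], [6, 30]])
        screen = mn.correlation_screen(_counts(mat), use_relative=False)
        assert screen.rho[0, 1] == pytest.approx(1.0)
        assert screen.q_fdr[0, 1] < 1e-6

    def test_rho_matches_rank_then_pearson_with_ties(self):
        x = np.array([3, 1, 4, 1, 5, 9], float)
        y = np.array([2, 7, 1, 8, 2, 8], float)
        mat = np.column_stack([x, y, np.arange(6) + 1]).astype(int)
        screen = mn.correlation_screen(_counts(mat), use_relative=False)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        ref = np.corrcoef(rx, ry)[0, 1]
        assert screen.rho[0, 1] == pytest.approx(ref, rel=1e-12)

    def test_constant_taxon_recorded_missing_and_never_an_edge(self):
        mat = np.column_stack([np.arange(6) + 1, np.full(6, 3), np.arange(6)[::-1] + 1])
        screen = mn.correlation_screen(_counts(mat), use_relative=False)
        assert math.isnan(screen.rho[0, 1]) and math.isnan(screen.rho[1, 2])
        net = mn.build_network(screen, rho_min=0.1, q_max=0.5)
        assert "T1" not in net.nodes

    def test_bh_adjustment_matches_upper_triangle_reference(self, rng):
        mat = rng.integers(1, 100, size=(10, 6))
        screen = mn.correlation_screen(_counts(mat), use_relative=False)
        iu = np.triu_indices(6, k=1)
        ref = stats.false_discovery_control(screen.p_raw[iu], method="bh")
        np.testing.assert_allclose(screen.q_fdr[iu], ref, rtol=1e-12)
        assert np.nanmax(screen.q_fdr) <= 1.0

    def test_requires_five_samples(self):
        with pytest.raises(ValueError):
            mn.correlation_screen(_counts(np.ones((4, 3), dtype=int)))


class TestBuildNetwork:
    def _screen(self, rho, q):
        m = rho.shape[0]
        return CorrelationScreen([f"T{i}" for i in range(m)], rho, np.full_like(rho, 0.01), q)

    def test_all_weak_correlations_give_empty_network(self):
        rho = np.full((3, 3), 0.5)
        np.fill_diagonal(rho, 1.0)
        with pytest.warns(UserWarning, match="empty network"):
            net = mn.build_network(self._screen(rho, np.full((3, 3), 1e-6)))
        assert net.graph.number_of_edges() == 0

    def test_hand_set_thresholds(self):
        rho = np.eye(4)
        q = np.ones((4, 4))
        # pair (0,1): strong and significant; (0,2): strong but q too big;
        # (1,3): significant but weak; (2,3): strong negative + significant
        rho[0, 1] = rho[1, 0] = 0.8
        q[0, 1] = q[1, 0] = 1e-5
        rho[0, 2] = rho[2, 0] = 0.9
        q[0, 2] = q[2, 0] = 0.01
        rho[1, 3] = rho[3, 1] = 0.3
        q[1, 3] = q[3, 1] = 1e-5
        rho[2, 3] = rho[3, 2] = -0.75
        q[2, 3] = q[3, 2] = 1e-4
        net = mn.build_network(self._screen(rho, q))
        assert sorted(map(tuple, map(sorted, net.graph.edges))) == [("T0", "T1"), ("T2", "T3")]
        pos = mn.build_network(self._screen(rho, q), positive_only=True)
        assert sorted(map(tuple, map(sorted, pos.graph.edges))) == [("T0", "T1")]

    def test_one_qualifying_pair(self):
        rho = np.eye(2)
        rho[0, 1] = rho[1, 0] = 0.95
        q = np.full((2, 2), 1e-9)
        net = mn.build_network(self._screen(rho, q))
        assert net.graph.number_of_nodes() == 2 and net.graph.number_of_edges() == 1


class TestSubgraphMetrics:
    def test_complete_graph_k4(self):
        m = _metrics_of(itertools.combinations("abcd", 2))
        assert (m.den, m.cc, m.cd, m.cb, m.avg_l) == (1.0, 1.0, 0.0, 0.0, 1.0)
        assert m.avg_k == 3.0

    def test_star_s4_centralizations_are_one(self):
        m = _metrics_of([("h", "a"), ("h", "b"), ("h", "c")])
        assert m.cd == pytest.approx(1.0) and m.cb == pytest.approx(1.0)

    def test_path_p4(self):
        m = _metrics_of([("a", "b"), ("b", "c"), ("c", "d")])
        assert m.avg_l == pytest.approx(10 / 6)
        assert m.cc == 0.0

    def test_undefined_below_two_nodes(self):
        m = _metrics_of([("a", "b")], nodes=["a"])
        assert not m.defined and m.n == 1

    def test_missing_presence_entry_is_an_error(self):
        net = _net_from_edges([("a", "b")])
        with pytest.raises(ValueError, match="presence undefined"):
            mn.sample_subgraph_metrics(net, {"a": True})

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 12))
            p = float(rng.uniform(0.15, 0.7))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            g.add_edge(0, 1)  # avoid the fully-isolated degenerate case
            net = CooccurrenceNetwork(g)
            m = mn.sample_subgraph_metrics(net, set(g.nodes))
            ref = brute_metrics(g.nodes, g.edges)
            for key in TOPO_COLUMNS:
                ours = getattr(m, key)
                if math.isnan(ref[key]):
                    assert math.isnan(ours)
                else:
                    assert ours == pytest.approx(ref[key], abs=1e-10), key

    def test_permutation_equivariance(self, rng):
        g = nx.gnp_random_graph(9, 0.4, seed=5)
        relabel = dict(zip(g.nodes, rng.permutation([f"X{i}" for i in range(9)])))
        h = nx.relabel_nodes(g, relabel)
        m1 = mn.sample_subgraph_metrics(CooccurrenceNetwork(g), set(g.nodes))
        m2 = mn.sample_subgraph_metrics(CooccurrenceNetwork(h), set(h.nodes))
        for key in TOPO_COLUMNS:
            assert getattr(m1, key) == pytest.approx(getattr(m2, key), abs=1e-12)

    def test_adding_an_edge_never_decreases_density_or_connectivity(self, rng):
        g = nx.gnp_random_graph(8, 0.3, seed=11)
        net = CooccurrenceNetwork(g)
        m1 = mn.sample_subgraph_metrics(net, set(g.nodes))
        missing = [e for e in itertools.combinations(g.nodes, 2) if not g.has_edge(*e)]
        g2 = g.copy()
        g2.add_edge(*missing[0])
        m2 = mn.sample_subgraph_metrics(CooccurrenceNetwork(g2), set(g2.nodes))
        assert m2.den >= m1.den and m2.avg_k >= m1.avg_k


class TestComplexityIndex:
    def test_rank_one_metrics_load_entirely_on_pc1(self, rng):
        base = rng.normal(size=10)
        metrics = pd.DataFrame(
            {c: base * (i + 1) for i, c in enumerate(TOPO_COLUMNS)},
            index=[f"S{i}" for i in range(10)],
        )
        ci = mn.complexity_index(metrics)
        assert ci.variance_explained[0] == pytest.approx(1.0, abs=1e-10)
        assert ci.variance_explained[1] == pytest.approx(0.0, abs=1e-10)

    def test_two_block_structure_separates_loadings(self, rng):
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        metrics = pd.DataFrame(
            {
                "n": a, "avg_k": a + rng.normal(0, 0.01, 200),
                "cb": b, "cc": b + rng.normal(0, 0.01, 200),
                "cd": a - rng.normal(0, 0.01, 200), "den": a,
                "avg_l": b,
            }
        )
        ci = mn.complexity_index(metrics)
        block_a = ["n", "avg_k", "cd", "den"]
        block_b = ["cb", "cc", "avg_l"]
        l1 = ci.loadings["net_pc1"].abs()
        l2 = ci.loadings["net_pc2"].abs()
        # each component concentrates on one block
        assert (l1[block_a].mean() > l1[block_b].mean()) != (
            l2[block_a].mean() > l2[block_b].mean()
        )

    def test_sign_convention_is_deterministic(self, rng):
        metrics = pd.DataFrame(
            rng.normal(size=(30, 7)), columns=list(TOPO_COLUMNS)
        )
        a = mn.complexity_index(metrics)
        b = mn.complexity_index(metrics.copy())
        pd.testing.assert_frame_equal(a.scores, b.scores)
        for col in ("net_pc1", "net_pc2"):
            k = a.loadings[col].abs().idxmax()
            assert a.loadings.loc[k, col] > 0

    def test_constant_column_dropped_with_warning(self, rng):
        metrics = pd.DataFrame(rng.normal(size=(20, 7)), columns=list(TOPO_COLUMNS))
        metrics["den"] = 1.0
        with pytest.warns(UserWarning, match="constant metric"):
            ci = mn.complexity_index(metrics)
        assert "den" not in ci.loadings.index

    def test_requires_three_defined_samples(self, rng):
        metrics = pd.DataFrame(rng.normal(size=(2, 7)), columns=list(TOPO_COLUMNS))
        with pytest.raises(ValueError):
            mn.complexity_index(metrics)


def _all_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _all_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


class TestModules:
    def test_two_disjoint_triangles(self):
        net = _net_from_edges(
            [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
        )
        part = mn.detect_modules(net, 0)
        assert len(set(part.assignment.values())) == 2
        assert part.assignment["a"] == part.assignment["b"] == part.assignment["c"]

    def test_complete_graph_is_one_module(self):
        net = _net_from_edges(itertools.combinations("abcde", 2))
        part = mn.detect_modules(net, 0)
        assert set(part.assignment.values()) == {0}

    def test_matches_exhaustive_modularity_maximization(self):
        """Two K4 blocks + one bridge: greedy equals the global optimum."""
        block1 = list(itertools.combinations("abcd", 2))
        block2 = list(itertools.combinations("wxyz", 2))
        edges = block1 + block2 + [("d", "w")]
        net = _net_from_edges(edges)
        g = net.graph
        best_q, best_part = -1.0, None
        for part in _all_partitions(sorted(g.nodes)):
            q = nx.algorithms.community.modularity(g, [set(p) for p in part])
            if q > best_q:
                best_q, best_part = q, part
        ours = mn.detect_modules(net, 0)
        grouped = {}
        for node, mid in ours.assignment.items():
            grouped.setdefault(mid, set()).add(node)
        assert sorted(map(sorted, grouped.values())) == sorted(map(sorted, best_part))
        assert ours.modularity == pytest.approx(best_q, abs=1e-12)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            mn.detect_modules(CooccurrenceNetwork(nx.Graph()), 0)


class TestDegreeDistribution:
    def test_exact_power_law_slope(self):
        # realize a degree sequence whose histogram is count(k) = 144/k^2 exactly
        degrees = [k for k in (1, 2, 3, 4, 6) for _ in range(144 // k**2)]
        g = nx.havel_hakimi_graph(degrees)
        assert sorted(d for _, d in g.degree()) == sorted(degrees)
        slope, r2 = mn.degree_distribution_summary(CooccurrenceNetwork(g))
        assert slope == pytest.approx(-2.0, abs=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_regular_graph_rejected(self):
        net = CooccurrenceNetwork(nx.cycle_graph(10))
        with pytest.raises(ValueError, match="distinct degrees"):
            mn.degree_distribution_summary(net)

    def test_preferential_attachment_graph_is_scale_free(self):
        g = nx.barabasi_albert_graph(500, 2, seed=0)
        slope, r2 = mn.degree_distribution_summary(CooccurrenceNetwork(g))
        assert slope < 0 and r2 > 0.7


class TestEndToEnd:
    def test_survey_network_pipeline(self, small_survey):
        merged = mn.merge_counts(small_survey.bacteria, small_survey.fungi)
        merged = mn.filter_taxa(merged)
        screen = mn.correlation_screen(merged)
        net = mn.build_network(screen)
        assert net.graph.number_of_edges() > 0
        # block-correlated taxa should dominate the edges
        metrics = mn.metrics_table(net, merged)
        assert metrics["defined"].all()
        ci = mn.complexity_index(metrics)
        assert ci.variance_explained[0] >= ci.variance_explained[1] > 0
        assert np.isfinite(ci.scores.to_numpy()).all()
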
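"""Graph metrics against hand computations and brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from cernaforge import (
    betweenness_centrality,
    closeness_centrality,
    fit_power_law,
    fitness_report,
    node_degree,
    topological_coefficient,
)
from cernaforge.datatypes import ValidationError

# ---------------------------------------------------------------------------
# independent oracles (pure adjacency-dict / matrix computations)

def brute_shortest_paths(adj, s, t):
    """All shortest s-t paths by exhaustive simple-path enumeration."""
    best: list[list] = []
    best_len = [float("inf")]

    def dfs(path):
        node = path[-1]
        if len(path) - 1 > best_len[0]:
            return
        if node == t:
            d = len(path) - 1
            if d < best_len[0]:
                best_len[0] = d
                best.clear()
            if d == best_len[0]:
                best.append(list(path))
            return
        for nb in adj[node]:
            if nb not in path:
                path.append(nb)
                dfs(path)
                path.pop()

    dfs([s])
    return best


def brute_betweenness(adj):
    nodes = sorted(adj)
    n = len(nodes)
    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = brute_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bc[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2
    return {v: (bc[v] / norm if norm else 0.0) for v in nodes}


def brute_closeness(adj):
    out = {}
    for s in adj:
        dists = []
        for t in adj:
            if t == s:
                continue
            paths = brute_shortest_paths(adj, s, t)
            if paths:
                dists.append(len(paths[0]) - 1)
        out[s] = len(dists) / sum(dists) if dists else 0.0
    return out


def brute_topological_coefficient(adj):
    """Matrix-algebra route: shared neighbours from A², J = A² + A."""
    nodes = sorted(adj)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for v, nbrs in adj.items():
        for u in nbrs:
            A[idx[v], idx[u]] = 1
    A2 = A @ A
    out = {}
    for v in nodes:
        i = idx[v]
        k = int(A[i].sum())
        if k <= 1:
            out[v] = 0.0
            continue
        js = [
            A2[i, j] + A[i, j]
            for j in range(n)
            if j != i and A2[i, j] > 0
        ]
        out[v] = float(np.mean(js)) / k if js else 0.0
    return out


def random_graph(rng, n_max=8):
    n = rng.integers(2, n_max + 1)
    p = rng.uniform(0.15, 0.8)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p:
            g.add_edge(i, j)
    return g


def as_adj(g):
    return {v: sorted(g[v]) for v in g}


# ---------------------------------------------------------------------------

class TestDegree:
    def test_triangle_all_two(self):
        deg, dist = node_degree(nx.cycle_graph(3))
        assert set(deg.values()) == {2}
        assert dist == {2: 3}

    def test_star_hub_and_leaves(self):
        deg, dist = node_degree(nx.star_graph(5))
        assert deg[0] == 5
        assert dist == {5: 1, 1: 5}

    def test_handshake_on_fixture(self, fixture_network):
        g = fixture_network.to_graph()
        deg, _ = node_degree(g)
        assert sum(deg.values()) == 2 * g.number_of_edges()


class TestTopologicalCoefficient:
    def test_complete_k4_all_one(self):
        tc = topological_coefficient(nx.complete_graph(4))
        # every other node shares 2 neighbours and is adjacent: J=3, k=3
        assert all(v == pytest.approx(1.0) for v in tc.values())

    def test_star_leaves_excluded_by_convention(self):
        tc = topological_coefficient(nx.star_graph(4))
        for leaf in range(1, 5):
            assert tc[leaf] == 0.0

    def test_path_endpoint(self):
        g = nx.path_graph(3)  # a-b-c
        tc = topological_coefficient(g)
        # a shares b with c, not adjacent: J=1, but k(a)=1 -> convention 0
        assert tc[0] == 0.0
        # b: no other node shares a neighbour with b
        assert tc[1] == 0.0

    def test_square_with_diagonal(self):
        # 0-1-2-3-0 plus diagonal 0-2: hand J values
        g = nx.cycle_graph(4)
        g.add_edge(0, 2)
        tc = topological_coefficient(g)
        # node 1 (nbrs {0,2}): partners 0 (shared {2}, adj) J=2, 2 (shared {0},
        # adj) J=2, 3 (shared {0,2}) J=2 -> mean 2 / k 2 = 1
        assert tc[1] == pytest.approx(1.0)

    def test_matches_matrix_oracle_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            g = random_graph(rng)
            tc = topological_coefficient(g)
            oracle = brute_topological_coefficient(as_adj(g))
            for v in g:
                assert tc[v] == pytest.approx(oracle[v], abs=1e-12)


class TestCloseness:
    def test_path_values(self):
        c = closeness_centrality(nx.path_graph(3))
        assert c[1] == pytest.approx(1.0)
        assert c[0] == pytest.approx(2 / 3)

    def test_complete_graph_all_one(self):
        c = closeness_centrality(nx.complete_graph(5))
        assert all(v == pytest.approx(1.0) for v in c.values())

    def test_disjoint_edges_component_local(self):
        g = nx.Graph([(0, 1), (2, 3)])
        c = closeness_centrality(g)
        assert all(v == pytest.approx(1.0) for v in c.values())

    def test_isolated_node_zero(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1, 2])
        g.add_edge(0, 1)
        assert closeness_centrality(g)[2] == 0.0


class TestBetweenness:
    def test_path_middle_one(self):
        b = betweenness_centrality(nx.path_graph(3))
        assert b[1] == pytest.approx(1.0)
        assert b[0] == 0.0

    def test_triangle_all_zero(self):
        b = betweenness_centrality(nx.cycle_graph(3))
        assert all(v == 0.0 for v in b.values())

    def test_star_hub_one(self):
        b = betweenness_centrality(nx.star_graph(4))
        assert b[0] == pytest.approx(1.0)

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(3)
        g = random_graph(rng)
        mapping = {v: f"node_{v}" for v in g}
        h = nx.relabel_nodes(g, mapping)
        bg = betweenness_centrality(g)
        bh = betweenness_centrality(h)
        cg = closeness_centrality(g)
        ch = closeness_centrality(h)
        for v in g:
            assert bg[v] == pytest.approx(bh[mapping[v]])
            assert cg[v] == pytest.approx(ch[mapping[v]])

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            g = random_graph(rng)
            adj = as_adj(g)
            b = betweenness_centrality(g)
            c = closeness_centrality(g)
            ob = brute_betweenness(adj)
            oc = brute_closeness(adj)
            for v in g:
                assert b[v] == pytest.approx(ob[v], abs=1e-10)
                assert c[v] == pytest.approx(oc[v], abs=1e-10)


class TestPowerLawFit:
    def test_exact_power_law_recovered(self):
        x = np.arange(1, 6, dtype=float)
        fit = fit_power_law(x, 2.0 * x**-1.0)
        assert fit.b == pytest.approx(-1.0, abs=1e-12)
        assert fit.a == pytest.approx(2.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_y_degenerate(self):
        fit = fit_power_law([1, 2, 3, 4], [5.0, 5.0, 5.0, 5.0])
        assert fit.b == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == 1.0

    def test_noise_reduces_r_squared(self):
        rng = np.random.default_rng(1)
        x = np.arange(1, 30, dtype=float)
        y = 3.0 * x**-1.5 * 10 ** rng.normal(0, 0.2, len(x))
        fit = fit_power_law(x, y)
        assert fit.r_squared < 1.0

    def test_nonpositive_dropped_then_too_few_refused(self):
        with pytest.raises(ValidationError, match=">= 3"):
            fit_power_law([1, 2, 3], [1.0, -1.0, 0.0])

    @given(
        a=st.floats(min_value=1e-3, max_value=1e3),
        b=st.floats(min_value=-3.0, max_value=3.0),
    )
    def test_parameter_recovery_property(self, a, b):
        x = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        fit = fit_power_law(x, a * x**b)
        assert fit.a == pytest.approx(a, rel=1e-6)
        assert fit.b == pytest.approx(b, abs=1e-9)


class TestFitnessReport:
    def test_fixture_reports_four_fits(self, fixture_network):
        rep = fitness_report(fixture_network.to_graph())
        assert set(rep.fits) == {
            "degree", "topological_coefficient", "closeness", "betweenness",
        }
        for f in rep.fits.values():
            assert 0.0 <= f.r_squared <= 1.0

    def test_star_degree_series_refused_others_reported(self):
        rep = fitness_report(nx.star_graph(5))
        assert "degree" in rep.errors  # only 2 distinct degrees
        assert "closeness" in rep.fits

    def test_preferential_attachment_degree_fit(self):
        g = nx.barabasi_albert_graph(300, 2, seed=5)
        rep = fitness_report(g)
        assert rep.fits["degree"].r_squared > 0.7
        assert rep.fits["degree"].b < 0

    def test_tripartite_violation_detected(self):
        g = nx.Graph()
        g.add_node("A", rna_class="mRNA")
        g.add_node("L", rna_class="lncRNA")
        g.add_node("m", rna_class="miRNA")
        g.add_edges_from([("A", "L"), ("A", "m"), ("L", "m")])
        with pytest.raises(ValidationError, match="mRNA–lncRNA"):
            fitness_report(g)

    def test_modes_differ_only_in_centrality_series(self, fixture_network):
        g = fixture_network.to_graph()
        r1 = fitness_report(g, mode="per_node")
        r2 = fitness_report(g, mode="per_degree")
        np.testing.assert_allclose(r1.series["degree"][1], r2.series["degree"][1])
        assert r1.fits["degree"].r_squared == pytest.approx(
            r2.fits["degree"].r_squared
        )
        assert len(r1.series["closeness"][0]) >= len(r2.series["closeness"][0])
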
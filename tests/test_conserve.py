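"""Threshold scans, graph filtration and Venn-style intersection."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import oligonet as on


def graph_from_edges(edges):
    g = nx.Graph()
    for a, b, w in edges:
        g.add_edge(a, b, rho=w)
    return g


class DSU:
    """Union-find used as an independent connectivity oracle."""

    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def components_bruteforce(g, t):
    kept = [(a, b) for a, b, d in g.edges(data=True) if abs(d["rho"]) >= t]
    nodes = {x for e in kept for x in e}
    if not nodes:
        return 0, 0, 0
    dsu = DSU(nodes)
    for a, b in kept:
        dsu.union(a, b)
    roots = {}
    for x in nodes:
        roots.setdefault(dsu.find(x), 0)
        roots[dsu.find(x)] += 1
    return len(roots), max(roots.values()), len(nodes)


class TestThresholdScan:
    def test_single_edge(self):
        g = graph_from_edges([("a", "b", 0.6)])
        curve = on.threshold_scan(g)
        at = curve.set_index("t")
        assert at.loc[0.60, "n_components"] == 1
        assert at.loc[0.61, "n_components"] == 0
        assert at.loc[0.60, "main_fraction"] == 1.0

    def test_uniform_clique(self):
        nodes = list(range(6))
        g = graph_from_edges(
            [(a, b, 0.7) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
        )
        curve = on.threshold_scan(g).set_index("t")
        assert curve.loc[0.70, "n_components"] == 1
        assert curve.loc[0.70, "main_fraction"] == 1.0
        assert curve.loc[0.71, "n_components"] == 0

    def test_matches_union_find_oracle(self, rng):
        nodes = list(range(15))
        edges = []
        for i in range(15):
            for j in range(i + 1, 15):
                if rng.random() < 0.4:
                    edges.append((i, j, rng.uniform(-1, 1)))
        g = graph_from_edges(edges)
        g.add_nodes_from(nodes)
        curve = on.threshold_scan(g)
        for _, row in curve.iterrows():
            n_comp, largest, n_alive = components_bruteforce(g, row["t"])
            assert row["n_components"] == n_comp
            if n_comp:
                assert row["largest_fraction"] == pytest.approx(largest / n_alive)
                assert row["main_fraction"] == pytest.approx(largest / 15)

    def test_main_fraction_nonincreasing(self, rng):
        edges = [
            (i, j, rng.uniform(0, 1))
            for i in range(12)
            for j in range(i + 1, 12)
            if rng.random() < 0.5
        ]
        curve = on.threshold_scan(graph_from_edges(edges))
        mf = curve["main_fraction"].to_numpy()
        assert (np.diff(mf) <= 1e-12).all()

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            on.threshold_scan(nx.Graph())


class TestChooseThreshold:
    def test_picks_last_threshold_keeping_main_component(self):
        # chain a-b-c-d with weights so the graph fragments above 0.62
        g = graph_from_edges(
            [("a", "b", 0.9), ("b", "c", 0.62), ("c", "d", 0.8), ("a", "c", 0.62)]
        )
        t, degraded = on.choose_threshold(on.threshold_scan(g))
        assert t == pytest.approx(0.62)
        assert not degraded

    def test_uniformly_weak_graph_degrades_to_floor(self):
        g = graph_from_edges([("a", "b", 0.3), ("b", "c", 0.4)])
        t, degraded = on.choose_threshold(on.threshold_scan(g))
        assert t == 0.5 and degraded

    def test_matches_exhaustive_search(self, rng):
        edges = [
            (i, j, rng.uniform(0.3, 0.95))
            for i in range(10)
            for j in range(i + 1, 10)
            if rng.random() < 0.6
        ]
        g = graph_from_edges(edges)
        curve = on.threshold_scan(g)
        t, degraded = on.choose_threshold(curve, floor=0.5, main_fraction=0.8)
        n_total = g.number_of_nodes()
        best = None
        for tt in curve["t"]:
            if tt < 0.5:
                continue
            n_comp, largest, _ = components_bruteforce(g, tt)
            if n_comp and largest / n_total >= 0.8:
                best = tt
        if best is None:
            assert degraded and t == 0.5
        else:
            assert t == pytest.approx(best)


class TestIntersection:
    def test_identical_graphs_fully_shared(self):
        g = graph_from_edges([("a", "b", 0.8), ("b", "c", 0.7)])
        gi, v, e = on.intersect_graphs(g, g.copy())
        assert v == 100.0 and e == 100.0
        assert gi.number_of_edges() == 2

    def test_edge_disjoint_graphs_share_vertices_only(self):
        ga = graph_from_edges([("a", "b", 0.8), ("c", "d", 0.8)])
        gb = graph_from_edges([("a", "c", 0.8), ("b", "d", 0.8)])
        gi, v, e = on.intersect_graphs(ga, gb)
        assert v == 100.0 and e == 0.0
        assert gi.number_of_edges() == 0

    def test_toy_pair_matches_hand_counted_venn(self):
        ga = graph_from_edges([("a", "b", 0.9), ("b", "c", 0.8), ("c", "d", 0.7)])
        gb = graph_from_edges([("a", "b", 0.6), ("b", "c", 0.9), ("b", "e", 0.8)])
        gi, v, e = on.intersect_graphs(ga, gb)
        # vertices: common {a,b,c}, union {a,b,c,d,e}; edges: common
        # {ab, bc}, union {ab, bc, cd, be}
        assert v == pytest.approx(100 * 3 / 5)
        assert e == pytest.approx(100 * 2 / 4)
        assert gi.edges["a", "b"]["rho"] == pytest.approx((0.9 + 0.6) / 2)

    def test_intersection_is_subgraph_of_both(self, rng):
        def rand_graph():
            return graph_from_edges(
                [
                    (i, j, rng.uniform(-1, 1))
                    for i in range(8)
                    for j in range(i + 1, 8)
                    if rng.random() < 0.5
                ]
            )

        ga, gb = rand_graph(), rand_graph()
        gi, v, e = on.intersect_graphs(ga, gb)
        assert v <= 100 and e <= 100
        for a, b in gi.edges:
            assert ga.has_edge(a, b) and gb.has_edge(a, b)


class TestSummary:
    def test_single_module(self):
        s = on.conservation_summary([72.6], [44.7])
        assert s["mean_vertex_pct"] == 72.6 and s["mean_edge_pct"] == 44.7

    def test_mean_equals_independent_resummation(self, rng):
        v = rng.uniform(0, 100, 9)
        e = rng.uniform(0, 100, 9)
        s = on.conservation_summary(v, e)
        assert s["mean_vertex_pct"] == pytest.approx(sum(v) / len(v))
        assert s["mean_edge_pct"] == pytest.approx(sum(e) / len(e))
        assert s["min_vertex_pct"] == pytest.approx(min(v))
        assert s["max_edge_pct"] == pytest.approx(max(e))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            on.conservation_summary([], [])


class TestConserveModule:
    def test_perturbed_module_is_least_conserved(self, rng):
        spec = on.CommunitySimSpec(seed=31, perturb_module=3)
        env = on.generate_env(spec)
        t1, t2, truth = on.generate_community(spec, env)
        net1 = on.sparcc(t1.counts, seed=311)
        net2 = on.sparcc(t2.counts, seed=312)
        mem = pd.Series(truth)
        epct = {}
        for m in range(1, spec.n_modules + 1):
            rep = on.conserve_module(net1.rho, net2.rho, mem.index[mem == m], module=m)
            epct[m] = rep.edge_pct
            assert 0 <= rep.vertex_pct <= 100 and 0 <= rep.edge_pct <= 100
        assert min(epct, key=epct.get) == 3
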
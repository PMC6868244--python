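"""Correlation screen, planar filtering, module hierarchy and hub calls."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from nigranet.pfn import (
    ModuleHierarchy,
    PlanarNetwork,
    build_pfn,
    correlation_screen,
    detect_modules,
    find_hubs,
)


def pair_table(rows):
    tbl = pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho"])
    tbl["abs_rho"] = tbl["rho"].abs()
    return tbl.sort_values(
        ["abs_rho", "gene_a", "gene_b"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)


def build_pfn_reference(sorted_pairs, nodes):
    """Naive greedy PMFG: full-graph planarity check per insertion."""
    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    n = g.number_of_nodes()
    max_edges = max(0, 3 * n - 6) if n >= 3 else (1 if n == 2 else 0)
    for row in sorted_pairs.itertuples(index=False):
        if g.number_of_edges() >= max_edges:
            break
        if row.gene_a == row.gene_b or g.has_edge(row.gene_a, row.gene_b):
            continue
        g.add_edge(row.gene_a, row.gene_b)
        if not nx.check_planarity(g, counterexample=False)[0]:
            g.remove_edge(row.gene_a, row.gene_b)
    return g


class TestCorrelationScreen:
    def test_duplicated_gene_tops_ranking(self, rng):
        x = rng.normal(size=40)
        mat = pd.DataFrame(
            np.vstack([x, x, rng.normal(size=(3, 40))]),
            index=["a", "a2", "c", "d", "e"],
        )
        tbl = correlation_screen(mat, fdr_cut=0.05)
        assert {tbl.iloc[0]["gene_a"], tbl.iloc[0]["gene_b"]} == {"a", "a2"}
        assert tbl.iloc[0]["rho"] == pytest.approx(1.0)

    def test_null_data_yields_no_significant_pairs(self, rng):
        mat = pd.DataFrame(rng.normal(size=(46, 100)))  # 1035 pairs
        mat.index = [f"g{i}" for i in range(46)]
        tbl = correlation_screen(mat, fdr_cut=0.05)
        assert len(tbl) <= 2

    def test_constructed_correlations_order(self, rng):
        # build vectors with exact sample correlations to x by Gram-Schmidt
        n = 50
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        rows = {"x": x}
        for name, r in [("a", 0.9), ("b", 0.5), ("c", 0.1)]:
            z = rng.normal(size=n)
            z = z - z.mean()
            z = z - (z @ x) / (x @ x) * x  # exactly orthogonal to x
            z = z / z.std()
            rows[name] = r * x + np.sqrt(1 - r * r) * z
        mat = pd.DataFrame(rows).T
        tbl = correlation_screen(mat, fdr_cut=1.0)
        with_x = tbl[(tbl["gene_a"] == "x") | (tbl["gene_b"] == "x")]
        partners = [
            (r.gene_a if r.gene_b == "x" else r.gene_b)
            for r in with_x.itertuples(index=False)
        ]
        got = dict(zip(partners, with_x["rho"].round(10)))
        assert got["a"] == pytest.approx(0.9, abs=1e-10)
        assert got["b"] == pytest.approx(0.5, abs=1e-10)
        assert got["c"] == pytest.approx(0.1, abs=1e-10)
        assert partners == ["a", "b", "c"]  # sorted by |rho| descending

    def test_constant_gene_dropped(self, rng):
        mat = pd.DataFrame(
            np.vstack([np.ones(30), rng.normal(size=(2, 30))]), index=["k", "a", "b"]
        )
        tbl = correlation_screen(mat, fdr_cut=1.0)
        assert "k" not in set(tbl["gene_a"]) | set(tbl["gene_b"])


class TestBuildPfn:
    def test_k4_fully_retained(self):
        genes = list("abcd")
        rows = [(u, v, 0.5) for i, u in enumerate(genes) for v in genes[i + 1:]]
        net = build_pfn(pair_table(rows), nodes=genes)
        assert net.graph.number_of_edges() == 6  # K4 is planar

    def test_k5_drops_exactly_lowest_weight_edge(self):
        genes = list("abcde")
        rows, w = [], 1.0
        pairs = [(u, v) for i, u in enumerate(genes) for v in genes[i + 1:]]
        for u, v in pairs:
            rows.append((u, v, w))
            w -= 0.05  # 10 distinct weights; ('d','e') is lowest
        net = build_pfn(pair_table(rows), nodes=genes)
        assert net.graph.number_of_edges() == 9
        assert not net.graph.has_edge("d", "e")

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_naive_reference(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(6, 30))
        genes = [f"g{i:02d}" for i in range(n)]
        rows = [
            (genes[i], genes[j], float(rng.uniform(-1, 1)))
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < 0.7
        ]
        tbl = pair_table(rows)
        ref = build_pfn_reference(tbl, genes)
        new = build_pfn(tbl, nodes=genes).graph
        assert set(map(frozenset, ref.edges)) == set(map(frozenset, new.edges))

    def test_always_planar_and_bounded(self, rng):
        for trial in range(25):
            n = int(rng.integers(4, 25))
            genes = [f"g{i:02d}" for i in range(n)]
            rows = [
                (genes[i], genes[j], float(rng.uniform(-1, 1)))
                for i in range(n)
                for j in range(i + 1, n)
            ]
            g = build_pfn(pair_table(rows), nodes=genes).graph
            assert g.number_of_edges() <= max(1, 3 * n - 6)
            assert nx.check_planarity(g, counterexample=False)[0]


def weighted_graph(edges):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w, sign=1)
    return g


class TestDetectModules:
    def test_two_disconnected_cliques_become_first_level_modules(self):
        g = nx.Graph()
        for offset, tag in ((0, "a"), (20, "b")):
            nodes = [f"{tag}{i:02d}" for i in range(12)]
            for i, u in enumerate(nodes):
                for v in nodes[i + 1:]:
                    g.add_edge(u, v, weight=0.8)
        net = PlanarNetwork(graph=g)
        h = detect_modules(net, min_size=5, n_perm=199, seed=0)
        first = h.children(ModuleHierarchy.ROOT)
        assert len(first) == 2
        assert {frozenset(h.modules[m]) for m in first} == {
            frozenset(f"a{i:02d}" for i in range(12)),
            frozenset(f"b{i:02d}" for i in range(12)),
        }

    def test_random_weighted_planar_graph_rarely_splits(self):
        splits = 0
        for seed in range(12):
            rng = np.random.default_rng(seed)
            genes = [f"g{i:02d}" for i in range(40)]
            rows = [
                (genes[i], genes[j], float(rng.uniform(0.2, 0.8)))
                for i in range(40)
                for j in range(i + 1, 40)
                if rng.random() < 0.3
            ]
            net = build_pfn(pair_table(rows), nodes=genes)
            h = detect_modules(net, min_size=10, n_perm=999, seed=seed)
            if len(h.modules) > 1 + sum(
                1 for _ in nx.connected_components(net.graph)
            ):
                splits += 1
        assert splits <= 1  # >=95% of seeds accept no split beyond components

    def _block_data(self, seed):
        rng = np.random.default_rng(seed)
        n, per = 150, 30
        genes = [f"g{i:03d}" for i in range(4 * per)]
        X = np.empty((4 * per, n))
        for b in range(4):
            f = rng.normal(size=n)
            for i in range(per):
                X[b * per + i] = 0.7 * f + np.sqrt(1 - 0.49) * rng.normal(size=n)
        return pd.DataFrame(X, index=genes), genes, per

    def test_recovers_planted_blocks(self):
        mat, genes, per = self._block_data(3)
        tbl = correlation_screen(mat, fdr_cut=0.05)
        net = build_pfn(tbl, nodes=genes)
        h = detect_modules(net, min_size=20, n_perm=999, seed=1, expr=mat)
        from sklearn.metrics import adjusted_rand_score

        leaf_of = {}
        for leaf in h.leaves():
            for x in h.modules[leaf]:
                leaf_of[x] = leaf
        truth = [i // per for i in range(len(genes))]
        pred = [leaf_of.get(g, "none") for g in genes]
        assert adjusted_rand_score(truth, pred) >= 0.7

    def test_children_partition_within_parent(self):
        mat, genes, per = self._block_data(5)
        tbl = correlation_screen(mat, fdr_cut=0.05)
        net = build_pfn(tbl, nodes=genes)
        h = detect_modules(net, min_size=20, n_perm=499, seed=2, expr=mat)
        for mid in h.modules:
            kids = h.children(mid)
            union = set()
            for k in kids:
                assert not (h.modules[k] & union)  # disjoint siblings
                union |= h.modules[k]
            assert union <= h.modules[mid]

    def test_min_size_monotone_in_reported_modules(self):
        mat, genes, per = self._block_data(7)
        tbl = correlation_screen(mat, fdr_cut=0.05)
        net = build_pfn(tbl, nodes=genes)
        h = detect_modules(net, min_size=10, n_perm=499, seed=3, expr=mat)
        assert set(h.reported(25)) <= set(h.reported(10))


class TestFindHubs:
    def test_star_center_is_unique_hub(self):
        g = nx.star_graph(10)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        net = PlanarNetwork(graph=g)
        h = ModuleHierarchy(
            modules={"M0": set(g.nodes)}, parent={"M0": None}, scale={"M0": 0}
        )
        hubs = find_hubs(net, h, n_perm=200, seed=0)
        assert set(hubs["M0"]) == {"n00"}

    def test_regular_ring_has_no_hubs(self):
        g = nx.cycle_graph(20)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        net = PlanarNetwork(graph=g)
        h = ModuleHierarchy(
            modules={"M0": set(g.nodes)}, parent={"M0": None}, scale={"M0": 0}
        )
        hubs = find_hubs(net, h, n_perm=200, seed=0)
        assert hubs["M0"] == {}

    def test_tiny_module_yields_no_hubs(self):
        g = nx.path_graph(2)
        g = nx.relabel_nodes(g, {0: "a", 1: "b"})
        net = PlanarNetwork(graph=g)
        h = ModuleHierarchy(modules={"M0": {"a", "b"}}, parent={"M0": None},
                            scale={"M0": 0})
        assert find_hubs(net, h, n_perm=50, seed=0)["M0"] == {}
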
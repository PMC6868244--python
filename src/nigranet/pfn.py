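"""Planar-filtered co-expression network and multiscale module hierarchy.

The network is built by greedy insertion of the strongest significant
correlations subject to graph planarity (a planar maximally filtered graph,
capped at 3n-6 edges; planarity is certified by the left-right test behind
:func:`networkx.check_planarity`). On top of the planar network a
parent-child module hierarchy is extracted by recursive multi-way modularity
partitioning: a module is split only when its observed Louvain modularity
exceeds the 95% quantile of modularities obtained from degree-preserving
rewirings of its own subnetwork, and at least two children reach a minimum
size. Within each accepted module, hub genes are those whose within-module
degree exceeds the 95% quantile of the maximum degree observed in
edge-count-matched random graphs on the module's nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import GlobalMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PlanarNetwork",
    "ModuleHierarchy",
    "correlation_screen",
    "build_pfn",
    "detect_modules",
    "find_hubs",
]


@dataclass
class PlanarNetwork:
    graph: nx.Graph
    built_from: str = "case"

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def to_edge_table(self) -> pd.DataFrame:
        rows = [
            {"gene_a": u, "gene_b": v, "weight": d["weight"], "sign": d["sign"]}
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight", "sign"])

    @classmethod
    def from_edge_table(
        cls, table: pd.DataFrame, nodes: list[str] | None = None,
        built_from: str = "case",
    ) -> "PlanarNetwork":
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(sorted(nodes))
        for row in table.itertuples(index=False):
            g.add_edge(row.gene_a, row.gene_b, weight=row.weight, sign=row.sign)
        return cls(graph=g, built_from=built_from)


@dataclass
class ModuleHierarchy:
    modules: dict[str, set[str]]
    parent: dict[str, str | None]
    scale: dict[str, int]
    hubs: dict[str, dict[str, int]] = field(default_factory=dict)

    ROOT = "M0"

    def children(self, mid: str) -> list[str]:
        return sorted(m for m, p in self.parent.items() if p == mid)

    def leaves(self) -> list[str]:
        withkids = set(self.parent.values())
        return sorted(m for m in self.modules if m not in withkids)

    def reported(self, min_size: int = 50) -> list[str]:
        """Modules (root excluded) with size strictly greater than min_size."""
        return sorted(
            m for m, gs in self.modules.items() if m != self.ROOT and len(gs) > min_size
        )

    @classmethod
    def from_json_obj(cls, obj: list[dict]) -> "ModuleHierarchy":
        return cls(
            modules={d["module"]: set(d["genes"]) for d in obj},
            parent={d["module"]: d["parent"] for d in obj},
            scale={d["module"]: d["scale"] for d in obj},
            hubs={d["module"]: dict(d.get("hubs", {})) for d in obj},
        )

    def to_json_obj(self) -> list[dict]:
        return [
            {
                "module": m,
                "parent": self.parent[m],
                "scale": self.scale[m],
                "genes": sorted(self.modules[m]),
                "hubs": dict(sorted(self.hubs.get(m, {}).items())),
            }
            for m in sorted(self.modules)
        ]


def correlation_screen(
    matrix: GlobalMatrix | pd.DataFrame, fdr_cut: float = 0.05
) -> pd.DataFrame:
    """All-pairs Pearson correlations with a BH-FDR significance filter.

    Returns pairs with fdr < ``fdr_cut`` sorted by |rho| descending, ties
    broken lexicographically on (gene_a, gene_b). Constant genes are dropped.
    """
    mat = matrix.matrix if isinstance(matrix, GlobalMatrix) else matrix
    n = mat.shape[1]
    if n < 3:
        raise ValueError("correlation screen requires >=3 samples")
    X = mat.to_numpy(dtype=float)
    sd = X.std(axis=1)
    const = sd == 0
    if const.any():
        logger.warning("correlation_screen: %d constant genes dropped", int(const.sum()))
        mat = mat.loc[~const]
        X = X[~const]
    genes = mat.index.to_numpy()
    R = np.corrcoef(X)
    iu, ju = np.triu_indices(len(genes), k=1)
    rho = np.clip(R[iu, ju], -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = np.abs(rho) * np.sqrt((n - 2) / (1.0 - rho**2))
    p = np.where(np.abs(rho) >= 1.0, 0.0, 2.0 * stats.t.sf(t, n - 2))
    fdr = multipletests(p, method="fdr_bh")[1]
    keep = fdr < fdr_cut
    tbl = pd.DataFrame(
        {
            "gene_a": genes[iu[keep]],
            "gene_b": genes[ju[keep]],
            "rho": rho[keep],
            "p_value": p[keep],
            "fdr": fdr[keep],
        }
    )
    tbl["abs_rho"] = tbl["rho"].abs()
    tbl = tbl.sort_values(
        ["abs_rho", "gene_a", "gene_b"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    return tbl


def build_pfn(
    sorted_pairs: pd.DataFrame,
    nodes: list[str] | None = None,
    built_from: str = "case",
) -> PlanarNetwork:
    """Greedy planar filtering: walk the sorted pair list, keep an edge iff
    the graph stays planar; stop at the 3n-6 planar bound."""
    g = nx.Graph()
    universe = sorted(
        (set(nodes) if nodes is not None else set())
        | set(sorted_pairs["gene_a"])
        | set(sorted_pairs["gene_b"])
    )
    g.add_nodes_from(universe)
    n = len(universe)
    max_edges = max(0, 3 * n - 6) if n >= 3 else (1 if n == 2 else 0)

    # A graph is planar iff each biconnected component is planar, so every
    # test can run on the touched bicomp only. The cache keeps, per bicomp,
    # its node set and edge count: edges inside a bicomp already at the
    # 3k-6 Euler bound are rejected outright, bridges are accepted outright,
    # and only genuine within-bicomp insertions or bicomp merges invoke the
    # certified left-right planarity test.
    root = {v: v for v in universe}  # union-find over connected components
    bc_info: list[tuple[set, int]] = []  # (node set, edge count)
    node_bc: dict[str, set[int]] = {v: set() for v in universe}

    def find(v):
        while root[v] != v:
            root[v] = root[root[v]]
            v = root[v]
        return v

    def euler_bound(k: int) -> int:
        return 3 * k - 6 if k >= 3 else 1

    def new_bicomp(nodes_set: set, n_edges: int) -> None:
        bc_info.append((nodes_set, n_edges))
        i = len(bc_info) - 1
        for v in nodes_set:
            node_bc[v].add(i)

    def merge_bicomp(a: str, b: str) -> int:
        """After adding edge (a,b) that closed a cycle across bicomps,
        rebuild the decomposition of the touched component."""
        comp = nx.node_connected_component(g, a)
        sub = g.subgraph(comp)
        # drop stale entries for this component, then re-add
        stale = set().union(*(node_bc[v] for v in comp)) if comp else set()
        for v in comp:
            node_bc[v] -= stale
        target = -1
        for bc in nx.biconnected_components(sub):
            e = sum(1 for u in bc for w in g[u] if w in bc) // 2
            new_bicomp(set(bc), e)
            if a in bc and b in bc:
                target = len(bc_info) - 1
        return target

    for row in sorted_pairs.itertuples(index=False):
        if g.number_of_edges() >= max_edges:
            break
        a, b = row.gene_a, row.gene_b
        if a == b or g.has_edge(a, b):
            continue
        attrs = {"weight": abs(row.rho), "sign": 1 if row.rho >= 0 else -1}
        shared = node_bc[a] & node_bc[b]
        if shared:  # two nodes share at most one bicomp
            i = shared.pop()
            bc_nodes, bc_edges = bc_info[i]
            if bc_edges >= euler_bound(len(bc_nodes)):
                continue  # bicomp is edge-maximal planar
            g.add_edge(a, b, **attrs)
            ok, _ = nx.check_planarity(g.subgraph(bc_nodes), counterexample=False)
            if ok:
                bc_info[i] = (bc_nodes, bc_edges + 1)
            else:
                g.remove_edge(a, b)
        elif find(a) != find(b):  # bridge between components: always planar
            g.add_edge(a, b, **attrs)
            root[find(a)] = find(b)
            new_bicomp({a, b}, 1)
        else:  # same component, distinct bicomps: cycle merges bicomps
            g.add_edge(a, b, **attrs)
            i = merge_bicomp(a, b)
            bc_nodes, bc_edges = bc_info[i]
            if bc_edges > euler_bound(len(bc_nodes)) or not nx.check_planarity(
                g.subgraph(bc_nodes), counterexample=False
            )[0]:
                g.remove_edge(a, b)
                merge_bicomp(a, b)  # restore decomposition without the edge
    return PlanarNetwork(graph=g, built_from=built_from)


RESOLUTIONS = (0.2, 0.35, 0.5, 0.75, 1.0)


MAX_GATE_PAIRS = 200_000


def _induced_subgraph(g: nx.Graph, order: list) -> nx.Graph:
    """Induced subgraph with deterministic (sorted) node and edge order.

    networkx subgraph views iterate the node filter set in hash order,
    which is process-dependent for string labels; community detection
    results must not depend on that."""
    member = set(order)
    sub = nx.Graph()
    sub.add_nodes_from(order)
    for u in order:
        for v in g[u]:
            if v in member and u < v:
                sub.add_edge(u, v, **g[u][v])
    return sub


def _split_pvalue(
    sub: nx.Graph,
    comms: list[set],
    n_perm: int,
    rng: np.random.Generator,
    corr: pd.DataFrame | None = None,
) -> float:
    """Permutation p-value for the cohesion of a candidate partition.

    Statistic: mean within-community gene-pair |correlation| minus the
    between-community mean, over ALL gene pairs of the module (not just
    kept edges); null: community labels permuted over genes. Testing the
    full correlation structure makes the gate immune to the community-like
    topology that planar filtering alone imprints (which fools rewiring and
    random-planar-graph modularity nulls alike) — for genes from one
    homogeneous correlation block, within and between pair strengths are
    exchangeable, so no split is ever certified. Falls back to the same
    test on edge weights against weight-vector permutation when no
    correlation matrix is supplied.
    """
    label = {}
    for i, c in enumerate(comms):
        for v in c:
            label[v] = i
    if corr is not None:
        genes = [g for g in sub.nodes if g in corr.index]
        lab = np.array([label[g] for g in genes])
        C = np.abs(corr.loc[genes, genes].to_numpy(dtype=float))
        n = len(genes)
        iu, ju = np.triu_indices(n, k=1)
        if len(iu) > MAX_GATE_PAIRS:
            pick = rng.choice(len(iu), size=MAX_GATE_PAIRS, replace=False)
            iu, ju = iu[pick], ju[pick]
        vals = C[iu, ju]

        def stat(labels: np.ndarray) -> float:
            within = labels[iu] == labels[ju]
            nw = int(within.sum())
            if nw == 0 or nw == len(vals):
                return 0.0
            return float(vals[within].mean() - vals[~within].mean())

        obs = stat(lab)
        null = np.array([stat(rng.permutation(lab)) for _ in range(n_perm)])
        return float((1 + np.sum(null >= obs)) / (n_perm + 1))

    w = np.array([d.get("weight", 1.0) for _, _, d in sub.edges(data=True)])
    within = np.array([label[u] == label[v] for u, v in sub.edges()])
    k, m = int(within.sum()), len(w)
    if k == 0 or k == m:
        return 1.0
    obs = w[within].mean() - w[~within].mean()
    perms = np.argsort(rng.random((n_perm, m)), axis=1)
    wp = w[perms]
    null = wp[:, :k].mean(axis=1) - wp[:, k:].mean(axis=1)
    return float((1 + np.sum(null >= obs)) / (n_perm + 1))


SOFT_POWER = 6  # soft-threshold exponent for the training-half structure graph


def _soft_threshold_graph(C: np.ndarray, beta: int = SOFT_POWER) -> nx.Graph:
    """Complete weighted graph on integer nodes with weights |r|^beta.

    Soft thresholding suppresses noise correlations smoothly (the
    co-expression convention) and is far more stable on half-sample
    correlation estimates than a hard top-m edge cut."""
    n = C.shape[0]
    W = np.abs(C) ** beta
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, k=1)
    vals = W[iu, ju]
    keep = vals > 1e-5
    for i, j, w in zip(iu[keep], ju[keep], vals[keep]):
        g.add_edge(int(i), int(j), weight=float(w))
    return g


def detect_modules(
    net: PlanarNetwork,
    min_size: int = 50,
    n_perm: int = 999,
    seed: int = 0,
    min_child: int = 10,
    alpha: float = 0.05,
    corr: pd.DataFrame | None = None,
    expr: pd.DataFrame | None = None,
) -> ModuleHierarchy:
    """Recursive permutation-gated multi-way modularity partitioning.

    Connected components form the first scale. Each module is then split by
    weight-aware Louvain clustering over an ascending resolution scan; the
    *coarsest* partition that yields >=2 children of >= ``min_child`` genes
    and passes the cohesion gate (an ``n_perm``-permutation test at alpha
    Bonferroni-shared across the scan) is accepted, and its children
    recurse. ``min_size`` only filters the *reported* module list, not the
    recursion.

    Supplying the gene x sample expression matrix ``expr`` (recommended;
    the pipeline always does) enables the sample-split gate: the samples
    are split once into two halves, candidate partitions are derived from
    soft-thresholded (|r|^6) correlation graphs of the first half, and the
    within- vs between-child separation of pair
    |correlations| is tested on the held-out half against a child-label
    permutation null. Optimizing and testing on the same correlations would
    certify noise-driven splits of perfectly homogeneous modules — an
    optimized partition always looks cohesive in-sample. With ``corr``
    (full-sample matrix) the gate tests all pair correlations without the
    split; with neither, it falls back to the kept edge weights.
    """
    if n_perm < 20 * len(RESOLUTIONS):
        logger.warning("detect_modules: n_perm=%d gives an unstable null", n_perm)
    rng = np.random.default_rng(seed)
    g = net.graph
    root = ModuleHierarchy.ROOT
    modules: dict[str, set[str]] = {root: set(g.nodes)}
    parent: dict[str, str | None] = {root: None}
    scale: dict[str, int] = {root: 0}
    counter = [0]
    alpha_scan = alpha / len(RESOLUTIONS)

    corr_train = corr_gate = None
    if expr is not None:
        cols = rng.permutation(expr.shape[1])
        half = expr.shape[1] // 2
        arr = expr.to_numpy(dtype=float)
        idx = expr.index
        corr_train = pd.DataFrame(
            np.corrcoef(arr[:, cols[:half]]), index=idx, columns=idx
        )
        corr_gate = pd.DataFrame(
            np.corrcoef(arr[:, cols[half:]]), index=idx, columns=idx
        )
    elif corr is not None:
        corr_gate = corr

    def new_id() -> str:
        counter[0] += 1
        return f"M{counter[0]}"

    def recurse(mid: str, genes: set[str], depth: int) -> None:
        order = sorted(genes)
        sub = _induced_subgraph(g, order)
        nn, m = sub.number_of_nodes(), sub.number_of_edges()
        if nn < 2 * min_child or m < 2:
            return
        # louvain runs on integer-node graphs: python's per-process string
        # hashing would otherwise make community aggregation order, and
        # hence the result, process-dependent
        if corr_train is not None:
            Ctr = corr_train.loc[order, order].to_numpy(dtype=float)
            sub_int = _soft_threshold_graph(Ctr)
        else:
            to_int = {v: i for i, v in enumerate(order)}
            sub_int = nx.Graph()
            sub_int.add_nodes_from(range(nn))
            for u, v, d in sub.edges(data=True):
                sub_int.add_edge(to_int[u], to_int[v], weight=d.get("weight", 1.0))
        accepted = None
        for res in RESOLUTIONS:
            comms = [
                {order[i] for i in c}
                for c in nx.community.louvain_communities(
                    sub_int, weight="weight", resolution=res,
                    seed=int(rng.integers(2**31 - 1)),
                )
            ]
            big = [c for c in comms if len(c) >= min_child]
            if len(big) < 2:
                continue
            if _split_pvalue(sub, comms, n_perm, rng, corr=corr_gate) <= alpha_scan:
                accepted = big
                break
        if accepted is None:
            return
        accepted.sort(key=lambda c: (-len(c), min(c)))
        for c in accepted:
            cid = new_id()
            modules[cid] = c
            parent[cid] = mid
            scale[cid] = depth
            recurse(cid, c, depth + 1)

    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    if len(comps) > 1:
        for c in comps:
            cid = new_id()
            modules[cid] = set(c)
            parent[cid] = root
            scale[cid] = 1
            recurse(cid, set(c), 2)
    else:
        recurse(root, modules[root], 1)
    return ModuleHierarchy(modules=modules, parent=parent, scale=scale)


def find_hubs(
    net: PlanarNetwork,
    hierarchy: ModuleHierarchy,
    n_perm: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[str, dict[str, int]]:
    """Permutation-tested within-module hubs.

    Null per module: random graphs with the module's node and edge counts;
    per draw the statistic is the maximum degree. A gene is a hub iff its
    within-module degree strictly exceeds the (1-alpha) null quantile.
    Modules with fewer than 3 nodes yield no hubs. Results are stored on the
    hierarchy and returned.
    """
    rng = np.random.default_rng(seed)
    hubs: dict[str, dict[str, int]] = {}
    for mid in sorted(hierarchy.modules):
        genes = sorted(hierarchy.modules[mid])
        sub = net.graph.subgraph(genes)
        nn, m = sub.number_of_nodes(), sub.number_of_edges()
        if nn < 3 or m < 1:
            hubs[mid] = {}
            continue
        null_max = np.empty(n_perm)
        for i in range(n_perm):
            r = nx.gnm_random_graph(nn, m, seed=int(rng.integers(2**31 - 1)))
            null_max[i] = max(d for _, d in r.degree)
        thr = np.quantile(null_max, 1.0 - alpha)
        hubs[mid] = {g: d for g, d in sub.degree if d > thr}
    hierarchy.hubs = hubs
    return hubs
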
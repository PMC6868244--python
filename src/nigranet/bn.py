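"""Consensus Bayesian regulatory network over a module's genes.

Expression is quantized per gene to three ordered levels (1-d k-means), and
directed structures are sampled by a Metropolis-Hastings walk over DAGs with
add/delete/reverse edge moves, scored by the BDeu (Dirichlet-multinomial)
marginal likelihood with equivalent sample size ``ess``. TF->target priors
act as hard constraints: a target may never be proposed as a parent of its
TF. Many chains are run from independent random initial structures; edges
present in strictly more than a support threshold (default 30%) of the
chains' final structures form the consensus network, which is then made
acyclic by iteratively removing the most weakly supported edge among those
lying on a cycle.

The per-family BDeu score for a child with r=3 levels and parent
configuration j is

    sum_j [ lnG(a_j) - lnG(a_j + n_j) ] + sum_jk [ lnG(a_jk + n_jk) - lnG(a_jk) ]

with a_j = ess / q, a_jk = ess / (r q), q the number of parent
configurations, and n the contingency counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "DiscretizedMatrix",
    "StructuralPrior",
    "ConsensusBN",
    "discretize",
    "family_score",
    "network_score",
    "mcmc_chain",
    "run_chains",
    "consensus",
    "deloop",
]

N_LEVELS = 3


@dataclass
class DiscretizedMatrix:
    """Gene x sample integer levels in {0,1,2} with per-gene breakpoints."""

    levels: pd.DataFrame
    breakpoints: dict[str, list[float]]
    n_levels: dict[str, int]
    excluded: list[str] = field(default_factory=list)


@dataclass
class StructuralPrior:
    """TF->target table; the derived forbidden set blocks target->TF edges."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def tf_set(self) -> set[str]:
        return {tf for tf, _ in self.pairs}

    @property
    def target_set(self) -> set[str]:
        return {t for _, t in self.pairs}

    def forbidden_edges(self) -> set[tuple[str, str]]:
        return {(t, tf) for tf, t in self.pairs}

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "StructuralPrior":
        return cls(pairs=[(str(a), str(b)) for a, b in table.iloc[:, :2].itertuples(index=False)])


@dataclass
class ConsensusBN:
    graph: nx.DiGraph  # edge attr: support
    n_chains: int
    support_threshold: float

    @property
    def acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.graph)

    def supports(self) -> dict[tuple[str, str], float]:
        return {(u, v): d["support"] for u, v, d in self.graph.edges(data=True)}

    def to_edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "support": d["support"]}
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["source", "target", "support"])


def discretize(
    matrix: pd.DataFrame, method: str = "kmeans3", seed: int = 0
) -> DiscretizedMatrix:
    """Per-gene quantization to <=3 ordered levels.

    ``kmeans3``: 1-d 3-cluster k-means, levels ordered by cluster mean.
    ``quantile``: tertile binning. Genes with fewer distinct values use
    fewer levels (warned); constant genes are excluded.
    """
    levels = {}
    breakpoints: dict[str, list[float]] = {}
    n_levels: dict[str, int] = {}
    excluded: list[str] = []
    rng = np.random.default_rng(seed)
    for gene, row in matrix.iterrows():
        x = row.to_numpy(dtype=float)
        distinct = np.unique(x)
        if distinct.size == 1:
            excluded.append(gene)
            continue
        k = min(N_LEVELS, distinct.size)
        if k < N_LEVELS:
            logger.warning("discretize: gene %s uses %d levels", gene, k)
        if method == "kmeans3":
            km = KMeans(n_clusters=k, n_init=5, random_state=int(rng.integers(2**31 - 1)))
            lab = km.fit_predict(x.reshape(-1, 1))
            order = np.argsort(km.cluster_centers_.ravel())
            remap = np.empty(k, dtype=int)
            remap[order] = np.arange(k)
            lev = remap[lab]
        elif method == "quantile":
            cuts = np.quantile(x, np.linspace(0, 1, k + 1)[1:-1])
            lev = np.searchsorted(cuts, x, side="right")
        else:
            raise ValueError(f"unknown discretization method {method!r}")
        bounds = [
            float((x[lev == j].max() + x[lev == j + 1].min()) / 2.0)
            for j in range(lev.max())
            if (lev == j).any() and (lev == j + 1).any()
        ]
        levels[gene] = lev
        breakpoints[gene] = bounds
        n_levels[gene] = int(lev.max()) + 1
    if excluded:
        logger.warning("discretize: %d constant genes excluded", len(excluded))
    lv = pd.DataFrame(levels, index=matrix.columns).T.astype(np.int8)
    return DiscretizedMatrix(levels=lv, breakpoints=breakpoints, n_levels=n_levels, excluded=excluded)


def _family_score_arr(
    child_col: np.ndarray, parent_cols: list[np.ndarray], ess: float
) -> float:
    """BDeu family score from integer level columns (r = 3)."""
    r = N_LEVELS
    q = r ** len(parent_cols)
    if parent_cols:
        cfg = np.zeros_like(child_col, dtype=np.int64)
        for p in parent_cols:
            cfg = cfg * r + p
        counts = np.bincount(cfg * r + child_col, minlength=q * r).reshape(q, r)
    else:
        counts = np.bincount(child_col, minlength=r).reshape(1, r)
    n_j = counts.sum(axis=1)
    a_j = ess / q
    a_jk = ess / (q * r)
    score = float(
        np.sum(gammaln(a_j) - gammaln(a_j + n_j))
        + np.sum(gammaln(a_jk + counts) - gammaln(a_jk))
    )
    return score


def family_score(
    data: DiscretizedMatrix, child: str, parents: tuple[str, ...], ess: float = 1.0
) -> float:
    """Public BDeu family score on a discretized matrix."""
    lv = data.levels
    return _family_score_arr(
        lv.loc[child].to_numpy(np.int64),
        [lv.loc[p].to_numpy(np.int64) for p in parents],
        ess,
    )


def network_score(
    data: DiscretizedMatrix, edges: list[tuple[str, str]], ess: float = 1.0
) -> float:
    """Total BDeu score of a structure (sum of family scores over all nodes)."""
    parents: dict[str, list[str]] = {g: [] for g in data.levels.index}
    for u, v in edges:
        parents[v].append(u)
    return sum(
        family_score(data, g, tuple(sorted(parents[g])), ess) for g in data.levels.index
    )


class _DagState:
    """Mutable DAG with parent sets, child adjacency and reachability checks."""

    def __init__(self, n: int):
        self.parents: list[set[int]] = [set() for _ in range(n)]
        self.children: list[set[int]] = [set() for _ in range(n)]

    def has_path(self, src: int, dst: int) -> bool:
        if src == dst:
            return True
        stack, seen = [src], {src}
        while stack:
            u = stack.pop()
            for w in self.children[u]:
                if w == dst:
                    return True
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return False

    def add(self, u: int, v: int) -> None:
        self.parents[v].add(u)
        self.children[u].add(v)

    def remove(self, u: int, v: int) -> None:
        self.parents[v].discard(u)
        self.children[u].discard(v)


def mcmc_chain(
    data: DiscretizedMatrix,
    prior: StructuralPrior | None = None,
    n_steps: int = 20000,
    max_parents: int = 3,
    seed: int = 0,
    ess: float = 1.0,
    score_cache: dict | None = None,
) -> set[tuple[str, str]]:
    """One Metropolis-Hastings chain over DAG structures; returns the edge
    set of the structure at the final step.

    The walk starts from a sparse random structure consistent with a random
    topological order, proposes add/delete/reverse edge moves, enforces
    acyclicity, the ``max_parents`` cap (default 3) and the forbidden
    (target->TF) edges at proposal time, and accepts with probability
    min(1, exp(delta BDeu)).
    """
    genes = list(data.levels.index)
    n = len(genes)
    if n < 2:
        raise ValueError("mcmc_chain requires >=2 genes")
    idx = {g: i for i, g in enumerate(genes)}
    cols = [data.levels.iloc[i].to_numpy(np.int64) for i in range(n)]
    forbidden: set[tuple[int, int]] = set()
    if prior is not None:
        for u, v in prior.forbidden_edges():
            if u in idx and v in idx:
                forbidden.add((idx[u], idx[v]))

    cache: dict[tuple[int, tuple[int, ...]], float] = (
        score_cache if score_cache is not None else {}
    )

    def fam(v: int, parents: set[int]) -> float:
        key = (v, tuple(sorted(parents)))
        s = cache.get(key)
        if s is None:
            s = _family_score_arr(cols[v], [cols[p] for p in key[1]], ess)
            cache[key] = s
        return s

    rng = np.random.default_rng(seed)
    state = _DagState(n)
    # random init: permutation order + sparse random edges
    perm = rng.permutation(n)
    p_edge = min(1.0, 2.0 / max(n - 1, 1))
    for a in range(n):
        for b in range(a + 1, n):
            u, v = int(perm[a]), int(perm[b])
            if (u, v) in forbidden or len(state.parents[v]) >= max_parents:
                continue
            if rng.random() < p_edge:
                state.add(u, v)

    exhausted = 0
    for _ in range(n_steps):
        u, v = rng.choice(n, size=2, replace=False)
        u, v = int(u), int(v)
        if v in state.children[u]:
            if rng.random() < 0.5:  # delete u->v
                delta = fam(v, state.parents[v] - {u}) - fam(v, state.parents[v])
                if delta >= 0 or rng.random() < np.exp(delta):
                    state.remove(u, v)
            else:  # reverse u->v
                if (v, u) in forbidden or len(state.parents[u]) >= max_parents:
                    exhausted += 1
                    continue
                state.remove(u, v)
                if state.has_path(u, v):  # another u~>v path: reversal cycles
                    state.add(u, v)
                    exhausted += 1
                    continue
                delta = (
                    fam(v, state.parents[v]) - fam(v, state.parents[v] | {u})
                    + fam(u, state.parents[u] | {v}) - fam(u, state.parents[u])
                )
                if delta >= 0 or rng.random() < np.exp(delta):
                    state.add(v, u)
                else:
                    state.add(u, v)
        else:  # add u->v
            if (
                (u, v) in forbidden
                or u in state.parents[v]
                or len(state.parents[v]) >= max_parents
                or state.has_path(v, u)
            ):
                exhausted += 1
                continue
            delta = fam(v, state.parents[v] | {u}) - fam(v, state.parents[v])
            if delta >= 0 or rng.random() < np.exp(delta):
                state.add(u, v)
    if exhausted:
        logger.debug("mcmc_chain: %d blocked proposals", exhausted)
    return {
        (genes[u], genes[v]) for u in range(n) for v in state.children[u]
    }


def run_chains(
    data: DiscretizedMatrix,
    prior: StructuralPrior | None = None,
    n_chains: int = 1000,
    n_steps: int = 20000,
    max_parents: int = 3,
    seed: int = 0,
    ess: float = 1.0,
) -> list[set[tuple[str, str]]]:
    """Independent chains from distinct random starts (shared score cache)."""
    ss = np.random.SeedSequence(seed)
    cache: dict = {}
    return [
        mcmc_chain(
            data,
            prior,
            n_steps=n_steps,
            max_parents=max_parents,
            seed=int(child.generate_state(1)[0] % (2**31 - 1)),
            ess=ess,
            score_cache=cache,
        )
        for child in ss.spawn(n_chains)
    ]


def consensus(
    chains: list[set[tuple[str, str]]], threshold: float = 0.30
) -> ConsensusBN:
    """Edges shared by strictly more than ``threshold`` of the chains."""
    if len(chains) < 2:
        raise ValueError("consensus requires >=2 chains")
    counts: dict[tuple[str, str], int] = {}
    for ch in chains:
        for e in ch:
            counts[e] = counts.get(e, 0) + 1
    g = nx.DiGraph()
    for (u, v), c in sorted(counts.items()):
        support = c / len(chains)
        if support > threshold:
            g.add_edge(u, v, support=support)
    return ConsensusBN(graph=g, n_chains=len(chains), support_threshold=threshold)


def deloop(net: ConsensusBN) -> tuple[ConsensusBN, list[tuple[str, str, float]]]:
    """Iteratively remove the most weakly supported edge among all edges
    lying on any directed cycle until the graph is acyclic.

    An edge lies on a cycle iff both endpoints share a nontrivial strongly
    connected component. Ties break lexicographically on (source, target).
    Returns the acyclic network and the removal log.
    """
    g = net.graph.copy()
    removed: list[tuple[str, str, float]] = []
    while True:
        scc_of: dict[str, int] = {}
        scc_size: dict[int, int] = {}
        for i, comp in enumerate(nx.strongly_connected_components(g)):
            scc_size[i] = len(comp)
            for node in comp:
                scc_of[node] = i
        cyc_edges = [
            (u, v)
            for u, v in g.edges
            if u == v or (scc_of[u] == scc_of[v] and scc_size[scc_of[u]] > 1)
        ]
        if not cyc_edges:
            break
        worst = min(cyc_edges, key=lambda e: (g.edges[e]["support"], e[0], e[1]))
        removed.append((worst[0], worst[1], g.edges[worst]["support"]))
        g.remove_edge(*worst)
    out = ConsensusBN(graph=g, n_chains=net.n_chains, support_threshold=net.support_threshold)
    assert out.acyclic
    return out, removed
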
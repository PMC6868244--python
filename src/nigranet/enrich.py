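"""Gene-set enrichment machinery.

Over-representation is measured by the one-sided hypergeometric tail
P(X >= k) (Fisher's exact test for enrichment) with fold enrichment
FE = (k/m) / (K/N) for an overlap k between a query of size m and a set of
size K in a background of size N, followed by Benjamini-Hochberg correction.
Module ranking scores each module against disease signatures over the
union-of-modules background; gene annotation tests the N-layer network
neighborhood of a gene against a catalog over the whole-network background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pfn import ModuleHierarchy, PlanarNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "Neighborhood",
    "fet",
    "bh_adjust",
    "rank_modules",
    "neighborhood",
    "neighborhood_enrichment",
    "annotate_gene",
    "read_gmt",
    "write_gmt",
]


@dataclass
class EnrichmentResult:
    query_name: str
    set_name: str
    k: int
    m: int
    K: int
    N: int
    fe: float
    p_value: float
    p_adj: float = np.nan


@dataclass
class Neighborhood:
    center: str
    h: int
    genes: set[str]
    include_center: bool = False


def fet(
    query: set[str],
    gene_set: set[str],
    background: set[str],
    query_name: str = "query",
    set_name: str = "set",
) -> EnrichmentResult:
    """One-sided over-representation test; genes outside the background are
    ignored on both sides, so results depend only on the declared universe."""
    if not background:
        raise ValueError("empty background")
    q = query & background
    s = gene_set & background
    if not q:
        raise ValueError("empty query after background restriction")
    N, m, K = len(background), len(q), len(s)
    k = len(q & s)
    p = float(stats.hypergeom.sf(k - 1, N, K, m))
    fe = (k / m) / (K / N) if K > 0 else np.nan
    return EnrichmentResult(query_name, set_name, k, m, K, N, fe, min(p, 1.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def rank_modules(
    hierarchy: ModuleHierarchy,
    signatures: dict[str, set[str]],
    min_size: int = 50,
    method: str = "sum_log",
) -> pd.DataFrame:
    """Rank reported modules by relevance to disease signatures.

    Background = union of genes over all modules. Each module x signature
    cell is a FET, BH-corrected across the whole grid. Relevance score:
    ``sum_log`` (default) sums -log10(p_adj) over signatures; ``rank_product``
    uses the geometric mean of per-signature ranks (smaller = better,
    reported negated so larger is always better).
    """
    mods = hierarchy.reported(min_size)
    if not mods:
        return pd.DataFrame(columns=["module", "score"]).set_index("module")
    background = set().union(*(hierarchy.modules[m] for m in hierarchy.modules))
    rows = []
    for m in mods:
        for sname in sorted(signatures):
            try:
                r = fet(hierarchy.modules[m], signatures[sname], background, m, sname)
            except ValueError:
                continue
            rows.append(r)
    grid = pd.DataFrame([r.__dict__ for r in rows])
    grid["p_adj"] = bh_adjust(grid["p_value"])
    pmat = grid.pivot(index="query_name", columns="set_name", values="p_adj")
    pmat = pmat.fillna(1.0).clip(lower=1e-300)
    if method == "sum_log":
        score = (-np.log10(pmat)).sum(axis=1)
    elif method == "rank_product":
        score = -np.exp(np.log(pmat.rank(axis=0)).mean(axis=1))
    else:
        raise ValueError(f"unknown ranking method {method!r}")
    out = pd.DataFrame({"score": score}).rename_axis("module")
    out = out.join(pmat.add_prefix("p_adj:"))
    out["size"] = [len(hierarchy.modules[m]) for m in out.index]
    return out.sort_values(["score", "module"], ascending=[False, True], kind="mergesort")


def _as_graph(net) -> nx.Graph | nx.DiGraph:
    if isinstance(net, PlanarNetwork):
        return net.graph
    if hasattr(net, "graph") and isinstance(net.graph, (nx.Graph, nx.DiGraph)):
        return net.graph
    return net


def neighborhood(
    net,
    gene: str,
    h: int = 2,
    include_center: bool = False,
    directed: bool = False,
) -> Neighborhood:
    """BFS ball of radius ``h`` around ``gene``.

    Directed networks are treated as undirected unless ``directed=True``
    (then only downstream edges are followed). h=0 yields just the center.
    """
    g = _as_graph(net)
    if gene not in g:
        raise KeyError(f"gene {gene!r} not in network")
    if isinstance(g, nx.DiGraph) and not directed:
        g = g.to_undirected(as_view=True)
    reach = nx.single_source_shortest_path_length(g, gene, cutoff=h)
    genes = set(reach)
    if not include_center:
        genes -= {gene}
    return Neighborhood(center=gene, h=h, genes=genes, include_center=include_center)


def neighborhood_enrichment(
    net,
    candidates: list[str],
    signature: set[str],
    h: int = 2,
    directed: bool = False,
) -> pd.DataFrame:
    """Per-candidate FET of the h-layer neighborhood against one signature.

    Background = all genes in the network. Candidates with empty
    neighborhoods get p=1/fe=0 (flagged by k=m=0 -> m=0 is invalid, so they
    are reported with p_value 1). BH across candidates.
    """
    g = _as_graph(net)
    background = set(g.nodes)
    cols = ["set_name", "k", "m", "K", "N", "fe", "p_value", "p_adj"]
    if not candidates:
        return pd.DataFrame(columns=cols).rename_axis("gene")
    rows = []
    for gene in sorted(candidates):
        nb = neighborhood(net, gene, h=h, directed=directed)
        if not nb.genes:
            rows.append(
                EnrichmentResult(gene, "signature", 0, 0, len(signature & background),
                                 len(background), 0.0, 1.0)
            )
            continue
        rows.append(fet(nb.genes, signature, background, gene, "signature"))
    tbl = pd.DataFrame([r.__dict__ for r in rows]).set_index("query_name")
    tbl.index.name = "gene"
    tbl["p_adj"] = bh_adjust(tbl["p_value"])
    return tbl


def annotate_gene(
    net,
    gene: str,
    catalog: dict[str, set[str]],
    h: int = 2,
) -> tuple[str | None, pd.DataFrame]:
    """Assign the top catalog term enriched in the gene's h-layer
    neighborhood (background = all network genes; ties: larger FE).

    Returns (top term or None, full BH-corrected table)."""
    g = _as_graph(net)
    background = set(g.nodes)
    nb = neighborhood(net, gene, h=h)
    if not nb.genes:
        logger.warning("annotate_gene: %s has an empty %d-layer neighborhood", gene, h)
        return None, pd.DataFrame()
    rows = []
    for name in sorted(catalog):
        try:
            rows.append(fet(nb.genes, catalog[name], background, gene, name))
        except ValueError:
            continue
    tbl = pd.DataFrame([r.__dict__ for r in rows]).set_index("set_name")
    tbl["p_adj"] = bh_adjust(tbl["p_value"])
    tbl = tbl.iloc[
        np.lexsort((tbl.index.to_numpy(), -tbl["fe"].to_numpy(), tbl["p_adj"].to_numpy()))
    ]
    top = tbl.index[0] if len(tbl) else None
    if top is not None and tbl.iloc[0]["p_adj"] >= 1.0 and tbl.iloc[0]["k"] == 0:
        top = None  # no overlap anywhere: no significant annotation
    return top, tbl


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT catalog (name, description, genes...)."""
    catalog: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has <3 fields")
        catalog[fields[0]] = {g for g in fields[2:] if g}
    return catalog


def write_gmt(catalog: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    """Write a GMT catalog; empty sets are skipped (the format requires at
    least one member per line) with a warning."""
    lines = []
    for name, genes in sorted(catalog.items()):
        if not genes:
            logger.warning("write_gmt: empty set %r skipped", name)
            continue
        lines.append("\t".join([name, description] + sorted(genes)))
    Path(path).write_text("\n".join(lines) + "\n")
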
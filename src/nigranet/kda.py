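"""Key driver analysis and the combined regulator ranking.

On the acyclic consensus network, a gene's downstream profile is the set of
nodes reachable along edge direction within ``h`` layers (default: all
descendants); key drivers are genes whose downstream count exceeds
mean + sigma_mult * sd of all nodes' counts. Final prioritization combines,
over the co-expression and Bayesian networks, each candidate's
neighborhood-enrichment rank r_ji into a discriminant value

    g_ji = (max_j(r_ji) + 1 - r_ji) / sum_j(r_ji),      G_j = prod_i g_ji

so that a smaller rank (stronger enrichment) yields a larger g, and the
product rewards genes ranked highly in both networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .bn import ConsensusBN

logger = logging.getLogger(__name__)

__all__ = [
    "DownstreamProfile",
    "RegulatorScore",
    "downstream_profiles",
    "call_key_drivers",
    "combine_rankings",
]


@dataclass
class DownstreamProfile:
    gene: str
    downstream_set: set[str]
    h: int | None  # None = unbounded

    @property
    def count(self) -> int:
        return len(self.downstream_set)


@dataclass
class RegulatorScore:
    gene: str
    ranks: dict[str, int]  # network -> r_ji
    g_values: dict[str, float]  # network -> g_ji
    G: float


def downstream_profiles(
    dag: ConsensusBN | nx.DiGraph, h: int | None = None
) -> list[DownstreamProfile]:
    """Per-gene downstream reach (directed BFS up to ``h`` layers)."""
    g = dag.graph if isinstance(dag, ConsensusBN) else dag
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("downstream_profiles requires an acyclic network (run deloop)")
    out = []
    for node in sorted(g.nodes):
        reach = nx.single_source_shortest_path_length(g, node, cutoff=h)
        ds = set(reach) - {node}
        out.append(DownstreamProfile(gene=node, downstream_set=ds, h=h))
    return out


def call_key_drivers(
    profiles: list[DownstreamProfile], sigma_mult: float = 2.0
) -> set[str]:
    """Key driver iff downstream count > mean + sigma_mult * sd of counts."""
    if len(profiles) < 5:
        raise ValueError("key driver analysis needs >=5 nodes")
    counts = np.array([p.count for p in profiles], dtype=float)
    thr = counts.mean() + sigma_mult * counts.std(ddof=0)
    return {p.gene for p in profiles if p.count > thr}


def combine_rankings(
    candidates: set[str],
    enrichment: dict[str, pd.DataFrame],
    rank_by: str = "p_adj",
) -> list[RegulatorScore]:
    """Combine per-network neighborhood-enrichment ranks into G scores.

    ``enrichment`` maps network name -> frame indexed by gene with columns
    ``p_adj`` (or ``p_value``) and ``fe``. Candidates missing from any
    network are excluded with a warning. Per network, candidates are ranked
    by enrichment p ascending (ties: fold enrichment descending, then gene
    id); output is sorted by G descending, ties by gene id.
    """
    usable = set(candidates)
    for name, tbl in enrichment.items():
        missing = usable - set(tbl.index)
        if missing:
            logger.warning(
                "combine_rankings: %d candidates missing from %s excluded",
                len(missing),
                name,
            )
            usable -= missing
    if not usable:
        return []
    ranks: dict[str, dict[str, int]] = {}
    for name, tbl in enrichment.items():
        sub = tbl.loc[sorted(usable)].copy()
        order = sorted(
            sub.index, key=lambda g: (sub.at[g, rank_by], -sub.at[g, "fe"], g)
        )
        ranks[name] = {g: i + 1 for i, g in enumerate(order)}

    scores = []
    for gene in sorted(usable):
        g_vals = {}
        for name, r in ranks.items():
            rj = np.array([r[g] for g in usable], dtype=float)
            g_vals[name] = (rj.max() + 1 - r[gene]) / rj.sum()
        G = float(np.prod(list(g_vals.values())))
        scores.append(
            RegulatorScore(gene=gene, ranks={n: r[gene] for n, r in ranks.items()},
                           g_values=g_vals, G=G)
        )
    scores.sort(key=lambda s: (-s.G, s.gene))
    return scores
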
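"""Key driver analysis and combined regulator ranking.

Calls key drivers on the consensus DAG (downstream reach above
mean + 2 sd), intersects them with the co-expression hubs, ranks the shared
candidates by DEG enrichment of their two-layer neighborhoods in each
network, combines the ranks into the G score (product of per-network
discriminant values), and annotates the top regulators against the gene-set
catalog. Writes the ranked regulator table.
"""

import argparse
import json
from pathlib import Path

import networkx as nx
import pandas as pd

from nigranet import bn as bn_mod
from nigranet import enrich, kda, pfn

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=str, default=str(ROOT / "results"))
    ap.add_argument("--layers", type=int, default=2)
    ap.add_argument("--sigma", type=float, default=2.0)
    args = ap.parse_args()
    outdir = Path(args.results)

    net = pfn.PlanarNetwork.from_edge_table(
        pd.read_csv(outdir / "pfn_edges.tsv", sep="\t")
    )
    hierarchy = pfn.ModuleHierarchy.from_json_obj(
        json.loads((outdir / "modules.json").read_text())
    )
    bn_tbl = pd.read_csv(outdir / "consensus_bn.tsv", sep="\t")
    g = nx.DiGraph()
    for row in bn_tbl.itertuples(index=False):
        g.add_edge(row.source, row.target, support=row.support)
    dag = bn_mod.ConsensusBN(graph=g, n_chains=0, support_threshold=0.30)

    profiles = kda.downstream_profiles(dag)
    key_drivers = kda.call_key_drivers(profiles, sigma_mult=args.sigma)
    hubs = set().union(*hierarchy.hubs.values()) if hierarchy.hubs else set()
    candidates = key_drivers & hubs
    print(f"{len(key_drivers)} BN key drivers, {len(hubs)} co-expression hubs, "
          f"{len(candidates)} shared candidates")

    degs = enrich.read_gmt(outdir / "deg_signature.gmt")
    signature = degs.get("DEG_up", set()) | degs.get("DEG_down", set())
    enrichment = {
        "coexpression": enrich.neighborhood_enrichment(
            net, sorted(candidates & set(net.graph.nodes)), signature, h=args.layers
        ),
        "bn": enrich.neighborhood_enrichment(
            dag, sorted(candidates & set(dag.graph.nodes)), signature, h=args.layers
        ),
    }
    ranking = kda.combine_rankings(candidates, enrichment)
    rows = [
        {
            "gene": s.gene,
            **{f"r_{n}": r for n, r in s.ranks.items()},
            **{f"g_{n}": v for n, v in s.g_values.items()},
            "G": s.G,
        }
        for s in ranking
    ]
    pd.DataFrame(rows).to_csv(outdir / "regulator_ranking.tsv", sep="\t", index=False)
    print("top regulators by combined G score:")
    for s in ranking[:5]:
        print(f"  {s.gene}  G={s.G:.4f}  ranks={s.ranks}")

    catalog = enrich.read_gmt(outdir / "data" / "gene_sets.gmt")
    for s in ranking[:3]:
        top_term, _ = enrich.annotate_gene(net, s.gene, catalog, h=args.layers)
        print(f"  {s.gene}: top neighborhood annotation = {top_term}")


if __name__ == "__main__":
    main()
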
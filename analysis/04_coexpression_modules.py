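"""Planar co-expression network, module hierarchy, hubs, module ranking.

Screens all gene pairs of the merged case matrix for significant Pearson
correlation, builds the planar maximally filtered network, extracts the
permutation-gated parent-child module hierarchy with hub genes, and ranks
reported modules (size > 50) by DEG-signature enrichment over the
union-of-modules background. Writes the edge list, hierarchy JSON and the
module ranking table.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from nigranet import enrich, pfn

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=str, default=str(ROOT / "results"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--min-module-size", type=int, default=50)
    args = ap.parse_args()
    outdir = Path(args.results)

    merged = pd.read_csv(outdir / "merged_case.tsv", sep="\t", index_col=0)
    pairs = pfn.correlation_screen(merged, fdr_cut=0.05)
    net = pfn.build_pfn(pairs, nodes=list(merged.index))
    print(f"PFN: {net.graph.number_of_nodes()} genes, "
          f"{net.graph.number_of_edges()} edges "
          f"(bound {3 * net.graph.number_of_nodes() - 6})")

    hierarchy = pfn.detect_modules(net, min_size=args.min_module_size,
                                   n_perm=999, seed=args.seed, expr=merged)
    pfn.find_hubs(net, hierarchy, n_perm=100, seed=args.seed + 1)
    reported = hierarchy.reported(args.min_module_size)
    print(f"hierarchy: {len(hierarchy.modules) - 1} modules, "
          f"{len(reported)} reported at size > {args.min_module_size}")

    net.to_edge_table().to_csv(outdir / "pfn_edges.tsv", sep="\t", index=False)
    (outdir / "modules.json").write_text(
        json.dumps(hierarchy.to_json_obj(), indent=1)
    )

    signatures = enrich.read_gmt(outdir / "deg_signature.gmt")
    table = enrich.rank_modules(hierarchy, signatures, min_size=args.min_module_size)
    table.to_csv(outdir / "module_ranking.tsv", sep="\t")
    if len(table):
        top = table.index[0]
        print(f"top module by DEG enrichment: {top} "
              f"({len(hierarchy.modules[top])} genes, score "
              f"{table.iloc[0]['score']:.1f})")


if __name__ == "__main__":
    main()
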
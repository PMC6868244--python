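"""Cross-study differential expression meta-analysis and stage correlation.

Pools per-study Hedges-g effects per gene (fixed effects, switching to
DerSimonian-Laird random effects when Cochran's Q is heterogeneous at
p < 0.05), calls DEGs at FDR < 0.05 and |pooled SMD| > 0.5, and screens
genes for Spearman correlation with the ordinal stage score in the cohort
carrying it. Writes the per-gene results table and the DEG signature GMT.
"""

import argparse
from pathlib import Path

import pandas as pd

from nigranet import enrich, meta

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=str, default=str(ROOT / "results"))
    args = ap.parse_args()
    outdir = Path(args.results)
    datadir = outdir / "data"

    processed = []
    probe_map = pd.read_csv(datadir / "probe_map.tsv", sep="\t", index_col=0)["gene"]
    for path in sorted(outdir.glob("processed_STUDY*.tsv")):
        sid = path.stem.split("_")[1]
        from nigranet.preprocess import ExpressionStudy

        exprs = pd.read_csv(path, sep="\t", index_col=0)
        meta_df = pd.read_csv(datadir / f"{sid}_meta.tsv", sep="\t", index_col=0)
        pm = pd.Series(exprs.index, index=exprs.index, name="gene")
        processed.append(
            ExpressionStudy(exprs=exprs, sample_meta=meta_df, probe_map=pm, study_id=sid)
        )

    res = meta.meta_analyze(processed)
    degs = meta.call_degs(res)
    res.to_csv(outdir / "meta_results.tsv", sep="\t")
    enrich.write_gmt(
        {"DEG_up": degs["up"], "DEG_down": degs["down"]},
        outdir / "deg_signature.gmt",
    )
    print(f"{len(res)} genes tested; DEGs: {len(degs['up'])} up, "
          f"{len(degs['down'])} down "
          f"(gate: FDR<0.05 and |pooled SMD|>0.5)")

    # stage correlation in the first cohort (carries the ordinal stage score)
    st = processed[0]
    stage = st.sample_meta.loc[st.exprs.columns, "stage"]
    sc = meta.stage_correlation(st.exprs, stage)
    sc.to_csv(outdir / "stage_correlation.tsv", sep="\t")
    sig = (sc["fdr"] < 0.05).sum()
    print(f"stage correlation in {st.study_id}: {sig} genes at FDR<0.05")


if __name__ == "__main__":
    main()
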
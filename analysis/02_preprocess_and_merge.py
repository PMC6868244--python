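"""Per-cohort preprocessing and Z-score merging into global matrices.

Quantile-normalizes each cohort, regresses out sex/age/RIN, collapses
duplicated probes to the highest-variance probe per gene, Z-scores each gene
within each study over both arms, and concatenates the case and control arms
across cohorts. Writes the processed per-study matrices and the two merged
matrices.
"""

import argparse
from pathlib import Path

import pandas as pd

from nigranet import preprocess

ROOT = Path(__file__).resolve().parents[1]


def load_studies(datadir: Path) -> list[preprocess.ExpressionStudy]:
    probe_map = pd.read_csv(datadir / "probe_map.tsv", sep="\t", index_col=0)["gene"]
    studies = []
    for epath in sorted(datadir.glob("STUDY*_exprs.tsv")):
        sid = epath.name.split("_")[0]
        studies.append(
            preprocess.ExpressionStudy(
                exprs=pd.read_csv(epath, sep="\t", index_col=0),
                sample_meta=pd.read_csv(datadir / f"{sid}_meta.tsv", sep="\t", index_col=0),
                probe_map=probe_map,
                study_id=sid,
            )
        )
    return studies


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=str, default=str(ROOT / "results" / "data"))
    ap.add_argument("--out", type=str, default=str(ROOT / "results"))
    args = ap.parse_args()
    datadir, outdir = Path(args.data), Path(args.out)
    outdir.mkdir(parents=True, exist_ok=True)

    processed = []
    for st in load_studies(datadir):
        st.check_min_per_group(5)
        st = preprocess.normalize_study(st)
        st = preprocess.regress_covariates(st, ["sex", "age", "rin"])
        st = preprocess.collapse_probes(st)
        st.exprs.to_csv(outdir / f"processed_{st.study_id}.tsv", sep="\t")
        processed.append(st)

    for arm in ("case", "control"):
        merged = preprocess.zscore_merge(processed, arm)
        merged.matrix.to_csv(outdir / f"merged_{arm}.tsv", sep="\t")
        merged.sample_meta.to_csv(outdir / f"merged_{arm}_meta.tsv", sep="\t")
        print(f"merged {arm}: {merged.matrix.shape[0]} genes x "
              f"{merged.matrix.shape[1]} samples")


if __name__ == "__main__":
    main()
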
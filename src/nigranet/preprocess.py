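"""Per-study preprocessing and cross-study merging.

The pipeline expects each cohort as an already-summarized probe x sample
intensity matrix. Preprocessing follows the usual microarray meta-analysis
recipe: log2 (when the matrix is on the linear scale), quantile
normalization, covariate regression (sex/age/RIN-style nuisance terms; the
case/control label is never regressed out), collapse of duplicated probes to
one row per gene by largest variance, and finally a within-study Z-score
transform — mean and sd taken over BOTH arms of the study — so that cohorts
from different platforms can be concatenated into global case and control
matrices without study-level location/scale artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionStudy",
    "GlobalMatrix",
    "normalize_study",
    "regress_covariates",
    "collapse_probes",
    "zscore_merge",
]


@dataclass
class ExpressionStudy:
    """One cohort: probe (or gene) x sample matrix plus sample metadata.

    ``log_scale`` flags whether intensities are already log2; ``probe_map``
    maps every matrix row id to a gene symbol.
    """

    exprs: pd.DataFrame
    sample_meta: pd.DataFrame
    probe_map: pd.Series
    study_id: str
    log_scale: bool = True

    def __post_init__(self) -> None:
        if self.exprs.columns.duplicated().any():
            raise ValueError(f"{self.study_id}: duplicated sample ids")
        missing = self.exprs.index.difference(self.probe_map.index)
        if len(missing):
            raise ValueError(
                f"{self.study_id}: {len(missing)} matrix rows missing from probe_map "
                f"(first: {missing[:3].tolist()})"
            )

    def group_sizes(self) -> pd.Series:
        return self.sample_meta["group"].value_counts()

    def check_min_per_group(self, min_per_group: int = 5) -> None:
        sizes = self.group_sizes()
        for arm in ("case", "control"):
            if sizes.get(arm, 0) < min_per_group:
                raise ValueError(
                    f"{self.study_id}: only {sizes.get(arm, 0)} {arm} samples "
                    f"(minimum {min_per_group} per group)"
                )


@dataclass
class GlobalMatrix:
    """Gene x sample Z-scores for one arm, concatenated across studies."""

    matrix: pd.DataFrame
    sample_meta: pd.DataFrame  # columns: study_id, group
    group: str


def _quantile_normalize(mat: pd.DataFrame) -> pd.DataFrame:
    """Map every column onto the across-column mean of sorted values; ties
    receive the mean of the reference values over their rank span."""
    arr = mat.to_numpy(dtype=float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        order = np.argsort(arr[:, j], kind="mergesort")
        col_sorted = arr[order, j]
        vals = ref.copy()
        # average reference values over each tied run
        start = 0
        for i in range(1, n + 1):
            if i == n or col_sorted[i] != col_sorted[start]:
                if i - start > 1:
                    vals[start:i] = vals[start:i].mean()
                start = i
        out[order, j] = vals
    return pd.DataFrame(out, index=mat.index, columns=mat.columns)


def normalize_study(study: ExpressionStudy) -> ExpressionStudy:
    """log2 (if linear scale) then quantile normalization."""
    mat = study.exprs
    if not study.log_scale:
        bad = mat <= 0
        if bad.to_numpy().any():
            rows, cols = np.where(bad.to_numpy())
            cells = [
                f"({mat.index[r]}, {mat.columns[c]})" for r, c in zip(rows[:5], cols[:5])
            ]
            raise ValueError(
                f"{study.study_id}: nonpositive intensities on linear scale at "
                + ", ".join(cells)
            )
        mat = np.log2(mat)
    return replace(study, exprs=_quantile_normalize(mat), log_scale=True)


def regress_covariates(
    study: ExpressionStudy, covariates: list[str]
) -> ExpressionStudy:
    """Replace each gene by intercept + OLS residuals on the named covariates.

    Categorical covariates are expanded to indicators; covariates missing
    from the metadata or constant across samples are skipped with a warning.
    The group label is never included.
    """
    meta = study.sample_meta.loc[study.exprs.columns]
    cols = []
    for name in covariates:
        if name == "group":
            raise ValueError("the case/control group label may not be regressed out")
        if name not in meta.columns:
            logger.warning("%s: covariate %r missing, skipped", study.study_id, name)
            continue
        col = meta[name]
        if col.nunique(dropna=False) < 2:
            logger.warning("%s: covariate %r constant, dropped", study.study_id, name)
            continue
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            cols.append(dummies)
        else:
            cols.append(col.astype(float).to_frame(name))
    if not cols:
        return study
    design = pd.concat(cols, axis=1)
    # center covariate columns so the intercept is the gene's mean level
    Xc = design.to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0, keepdims=True)
    X = np.column_stack([np.ones(len(design)), Xc])
    Y = study.exprs.to_numpy(dtype=float).T  # samples x genes
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        logger.warning(
            "%s: rank-deficient covariate design (rank %d of %d); "
            "redundant terms absorbed by least squares",
            study.study_id,
            rank,
            X.shape[1],
        )
    resid = Y - X @ beta
    out = (resid + beta[0][None, :]).T  # keep the intercept: original scale
    return replace(
        study, exprs=pd.DataFrame(out, index=study.exprs.index, columns=study.exprs.columns)
    )


def collapse_probes(study: ExpressionStudy) -> ExpressionStudy:
    """One row per gene: the probe with the largest across-sample variance
    (ties broken toward the lexicographically smallest probe id)."""
    var = study.exprs.var(axis=1, ddof=1)
    tbl = pd.DataFrame(
        {"gene": study.probe_map.loc[study.exprs.index].to_numpy(), "var": var}
    )
    # deterministic: sort by gene, then variance descending, then probe id
    tbl = (
        tbl.rename_axis("probe")
        .reset_index()
        .sort_values(["gene", "var", "probe"], ascending=[True, False, True], kind="mergesort")
    )
    chosen = tbl.groupby("gene", sort=True).first()
    ties = tbl.groupby("gene")["var"].apply(lambda v: (v == v.max()).sum() > 1)
    if ties.any():
        logger.info(
            "%s: %d genes had tied probe variances; smallest probe id kept",
            study.study_id,
            int(ties.sum()),
        )
    mat = study.exprs.loc[chosen["probe"]]
    mat.index = chosen.index
    new_map = pd.Series(chosen.index, index=chosen.index, name="gene")
    return replace(study, exprs=mat, probe_map=new_map)


def zscore_merge(studies: list[ExpressionStudy], arm: str) -> GlobalMatrix:
    """Within each study, Z-score every gene over ALL of that study's samples
    (both arms); then concatenate the requested arm's columns across studies.

    Genes are restricted to those present in every study; a gene with zero
    within-study sd is set to 0 there with a warning.
    """
    if arm not in ("case", "control"):
        raise ValueError("arm must be 'case' or 'control'")
    if len(studies) < 1:
        raise ValueError("no studies to merge")
    shared = sorted(set.intersection(*(set(s.exprs.index) for s in studies)))
    if not shared:
        raise ValueError("no genes shared across all studies")
    dropped = len(set.union(*(set(s.exprs.index) for s in studies))) - len(shared)
    if dropped:
        logger.info("zscore_merge: %d genes absent from some study dropped", dropped)

    blocks, meta_rows = [], []
    for st in studies:
        mat = st.exprs.loc[shared]
        mu = mat.mean(axis=1)
        sd = mat.std(axis=1, ddof=1)
        zero = sd == 0
        if zero.any():
            logger.warning(
                "%s: %d constant genes set to 0 after Z-transform",
                st.study_id,
                int(zero.sum()),
            )
            sd = sd.replace(0.0, np.inf)
        z = mat.sub(mu, axis=0).div(sd, axis=0)
        keep = st.sample_meta.index[st.sample_meta["group"] == arm]
        cols = z[keep]
        cols.columns = [f"{st.study_id}:{c}" for c in keep]
        blocks.append(cols)
        for c in keep:
            meta_rows.append({"sample": f"{st.study_id}:{c}", "study_id": st.study_id, "group": arm})
    merged = pd.concat(blocks, axis=1)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return GlobalMatrix(matrix=merged, sample_meta=meta, group=arm)
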
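"""Cross-study differential-expression meta-analysis.

Per gene and study, the effect size is Hedges' g — the case-minus-control
standardized mean difference with the small-sample bias correction
J = 1 - 3/(4(n1+n2-2)-1) — with sampling variance
v = (n1+n2)/(n1*n2) + g^2/(2(n1+n2)). Studies are pooled by inverse-variance
weighting; Cochran's Q tests heterogeneity against chi^2(k-1), and when the
heterogeneity p-value falls below 0.05 the gene is re-pooled under a
DerSimonian-Laird random-effects model with tau^2 = max(0, (Q-(k-1)) /
(Sum w - Sum w^2 / Sum w)). Differential expression is called at the joint
gate FDR < 0.05 (Benjamini-Hochberg across all tested genes) and
|pooled SMD| > 0.5. An ordinal-stage (Braak-like) screen correlates each
gene with the stage score by Spearman's rho with midranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import ExpressionStudy

logger = logging.getLogger(__name__)

__all__ = [
    "StudyEffect",
    "MetaGeneResult",
    "StageCorrelation",
    "study_effect",
    "pool_gene",
    "meta_analyze",
    "call_degs",
    "stage_correlation",
]

HET_ALPHA = 0.05  # heterogeneity gate for switching to random effects
DEG_FDR = 0.05
DEG_SMD = 0.5


@dataclass
class StudyEffect:
    gene: str
    study_id: str
    g: float  # Hedges' g, case - control
    v: float  # sampling variance
    n_case: int
    n_control: int


@dataclass
class MetaGeneResult:
    gene: str
    effects: list[StudyEffect] = field(repr=False)
    Q: float
    p_het: float
    tau2: float
    model: str  # "fixed" | "random"
    pooled_smd: float
    se_pooled: float
    p_value: float
    fdr: float = np.nan
    is_deg: bool = False
    direction: str = "none"


@dataclass
class StageCorrelation:
    gene: str
    rho: float
    p_value: float
    fdr: float = np.nan
    sign: str = "none"


def _hedges(
    mean_c: float, mean_k: float, s2_c: float, s2_k: float, n_c: int, n_k: int
) -> tuple[float, float]:
    """(g, v) for case stats (mean_c, s2_c, n_c) vs control (mean_k, s2_k, n_k)."""
    df = n_c + n_k - 2
    s_pooled = np.sqrt(((n_c - 1) * s2_c + (n_k - 1) * s2_k) / df)
    d = (mean_c - mean_k) / s_pooled
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * d
    v = (n_c + n_k) / (n_c * n_k) + g * g / (2.0 * (n_c + n_k))
    return float(g), float(v)


def study_effect(
    case_values: np.ndarray,
    control_values: np.ndarray,
    gene: str = "",
    study_id: str = "",
) -> StudyEffect:
    """Hedges' g for one gene in one study."""
    case = np.asarray(case_values, dtype=float)
    ctrl = np.asarray(control_values, dtype=float)
    if case.size < 2 or ctrl.size < 2:
        raise ValueError("study_effect requires >=2 samples per group")
    if not (np.isfinite(case).all() and np.isfinite(ctrl).all()):
        raise ValueError("non-finite expression values")
    s2_c, s2_k = case.var(ddof=1), ctrl.var(ddof=1)
    if (case.size - 1) * s2_c + (ctrl.size - 1) * s2_k == 0:
        raise ValueError(f"zero pooled sd for gene {gene!r} in study {study_id!r}")
    g, v = _hedges(case.mean(), ctrl.mean(), s2_c, s2_k, case.size, ctrl.size)
    return StudyEffect(gene, study_id, g, v, case.size, ctrl.size)


def pool_gene(effects: list[StudyEffect]) -> MetaGeneResult:
    """Inverse-variance pooling with the heterogeneity-gated model choice."""
    if len(effects) < 2:
        raise ValueError("pool_gene requires effects from >=2 studies")
    g = np.array([e.g for e in effects])
    v = np.array([e.v for e in effects])
    k = len(effects)
    w = 1.0 / v
    pooled_fe = float(np.sum(w * g) / np.sum(w))
    Q = float(np.sum(w * (g - pooled_fe) ** 2))
    p_het = float(stats.chi2.sf(Q, k - 1))
    if p_het < HET_ALPHA:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (Q - (k - 1)) / denom)
        w_star = 1.0 / (v + tau2)
        pooled = float(np.sum(w_star * g) / np.sum(w_star))
        se = float(1.0 / np.sqrt(np.sum(w_star)))
        model = "random"
    else:
        tau2 = 0.0
        pooled, se, model = pooled_fe, float(1.0 / np.sqrt(np.sum(w))), "fixed"
    p = float(2.0 * stats.norm.sf(abs(pooled / se)))
    return MetaGeneResult(
        gene=effects[0].gene,
        effects=effects,
        Q=Q,
        p_het=p_het,
        tau2=tau2,
        model=model,
        pooled_smd=pooled,
        se_pooled=se,
        p_value=p,
    )


def meta_analyze(
    studies: list[ExpressionStudy], min_per_group: int = 2
) -> pd.DataFrame:
    """Vectorized per-gene meta-analysis across collapsed studies.

    Returns a gene-indexed frame with Q, p_het, tau2, model, pooled_smd,
    se, p_value, fdr, is_deg and direction; genes must be present in every
    study (rows are intersected). Genes with zero pooled sd in any study are
    excluded with a warning.
    """
    shared = sorted(set.intersection(*(set(s.exprs.index) for s in studies)))
    if not shared:
        raise ValueError("no genes shared across studies")
    G = np.empty((len(shared), len(studies)))
    V = np.empty_like(G)
    bad = np.zeros(len(shared), dtype=bool)
    for j, st in enumerate(studies):
        grp = st.sample_meta.loc[st.exprs.columns, "group"].to_numpy()
        mat = st.exprs.loc[shared].to_numpy(dtype=float)
        case, ctrl = mat[:, grp == "case"], mat[:, grp == "control"]
        n_c, n_k = case.shape[1], ctrl.shape[1]
        if n_c < min_per_group or n_k < min_per_group:
            raise ValueError(f"{st.study_id}: fewer than {min_per_group} per group")
        df = n_c + n_k - 2
        sp2 = ((n_c - 1) * case.var(axis=1, ddof=1) + (n_k - 1) * ctrl.var(axis=1, ddof=1)) / df
        zero = sp2 == 0
        bad |= zero
        sp2 = np.where(zero, np.nan, sp2)
        d = (case.mean(axis=1) - ctrl.mean(axis=1)) / np.sqrt(sp2)
        jcor = 1.0 - 3.0 / (4.0 * df - 1.0)
        g = jcor * d
        G[:, j] = g
        V[:, j] = (n_c + n_k) / (n_c * n_k) + g * g / (2.0 * (n_c + n_k))
    if bad.any():
        logger.warning("meta_analyze: %d genes with zero pooled sd excluded", int(bad.sum()))

    k = len(studies)
    W = 1.0 / V
    pooled_fe = np.sum(W * G, axis=1) / np.sum(W, axis=1)
    Q = np.sum(W * (G - pooled_fe[:, None]) ** 2, axis=1)
    p_het = stats.chi2.sf(Q, k - 1)
    denom = np.sum(W, axis=1) - np.sum(W**2, axis=1) / np.sum(W, axis=1)
    tau2 = np.where(p_het < HET_ALPHA, np.maximum(0.0, (Q - (k - 1)) / denom), 0.0)
    W_star = 1.0 / (V + tau2[:, None])
    pooled = np.sum(W_star * G, axis=1) / np.sum(W_star, axis=1)
    se = 1.0 / np.sqrt(np.sum(W_star, axis=1))
    p = 2.0 * stats.norm.sf(np.abs(pooled / se))

    res = pd.DataFrame(
        {
            "Q": Q,
            "p_het": p_het,
            "tau2": tau2,
            "model": np.where(p_het < HET_ALPHA, "random", "fixed"),
            "pooled_smd": pooled,
            "se_pooled": se,
            "p_value": p,
            "mean_smd": G.mean(axis=1),
        },
        index=pd.Index(shared, name="gene"),
    )
    for j, st in enumerate(studies):
        res[f"g_{st.study_id}"] = G[:, j]
        res[f"v_{st.study_id}"] = V[:, j]
    res = res.loc[~bad]
    res["fdr"] = multipletests(res["p_value"], method="fdr_bh")[1]
    res["is_deg"] = (res["fdr"] < DEG_FDR) & (res["pooled_smd"].abs() > DEG_SMD)
    res["direction"] = np.where(
        res["is_deg"], np.where(res["pooled_smd"] > 0, "up", "down"), "none"
    )
    return res


def call_degs(results: pd.DataFrame) -> dict[str, set[str]]:
    """Up/down DEG signature from a meta_analyze frame (joint FDR+SMD gate)."""
    if len(results) == 0:
        return {"up": set(), "down": set()}
    return {
        "up": set(results.index[(results["is_deg"]) & (results["pooled_smd"] > 0)]),
        "down": set(results.index[(results["is_deg"]) & (results["pooled_smd"] < 0)]),
    }


def stage_correlation(
    matrix: pd.DataFrame, stage_scores: pd.Series
) -> pd.DataFrame:
    """Per-gene Spearman correlation with an ordinal stage score.

    ``matrix`` is gene x sample; ``stage_scores`` indexed by the same sample
    ids. Midranks handle ties; p-values use the t approximation and are
    BH-corrected across genes.
    """
    stage = stage_scores.loc[matrix.columns].to_numpy(dtype=float)
    if np.all(stage == stage[0]):
        raise ValueError("stage score is constant across samples")
    n = matrix.shape[1]
    ranks_x = stats.rankdata(matrix.to_numpy(dtype=float), axis=1)
    ranks_s = stats.rankdata(stage)
    rx = ranks_x - ranks_x.mean(axis=1, keepdims=True)
    rs = ranks_s - ranks_s.mean()
    denom = np.sqrt((rx**2).sum(axis=1) * (rs**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx @ rs) / denom
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = np.where(np.abs(rho) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    p = np.where(np.isnan(rho), 1.0, p)
    out = pd.DataFrame(
        {"rho": rho, "p_value": p}, index=matrix.index.rename("gene")
    )
    out["fdr"] = multipletests(out["p_value"].fillna(1.0), method="fdr_bh")[1]
    out["sign"] = np.where(
        out["fdr"] < 0.05, np.where(out["rho"] > 0, "positive", "negative"), "none"
    )
    return out
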
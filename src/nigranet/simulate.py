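"""Synthetic multi-cohort expression generator with planted ground truth.

Emulates the situation the pipeline is built for: several small case/control
microarray cohorts of a degenerating brain region, each on its own platform
(additive per-gene batch offsets plus a multiplicative scale), with duplicated
probes per gene, nuisance covariates (sex, age, RIN), an ordinal
disease-stage score, block/hierarchical co-expression driven by latent
factors, a fraction of disease-module genes carrying a planted case-control
standardized mean difference, and a planted regulatory DAG rooted at a "key
driver" inside the disease module.

The generative model per gene, study and sample is

    y = scale_s * (lambda_P * F_P + lambda_C * F_C + effect + covariates
                   + sqrt(1 - lambda_P^2 - lambda_C^2) * eps) + batch_{g,s}

with unit marginal variance before batch/covariate/effect terms, so a planted
effect delta is (up to a small severity-variance inflation) the true SMD.
The planted effect enters as delta_g * severity_k where severity has mean 1
in cases and 0 in controls, which ties differential expression to the ordinal
stage trait and makes stage correlation a recoverable signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ExpressionStudy

__all__ = [
    "DagSpec",
    "SimConfig",
    "SimTruth",
    "generate_cohorts",
    "generate_gene_sets",
    "generate_tf_prior",
    "sample_dag_data",
    "default_dag_spec",
    "write_cohorts",
]


@dataclass
class DagSpec:
    """Planted regulatory DAG over genes of the disease module.

    ``edges`` are (parent, child) index pairs into the disease module's gene
    list; ``root`` is the index of the planted key driver; ``fidelity`` is the
    probability that a child copies its (mean-rounded) parent level in the
    categorical conditional tables used by :func:`sample_dag_data`.
    """

    n_nodes: int
    edges: tuple[tuple[int, int], ...]
    root: int = 0
    fidelity: float = 0.85

    def validate(self) -> None:
        import networkx as nx

        g = nx.DiGraph(self.edges)
        g.add_nodes_from(range(self.n_nodes))
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("dag_spec edges contain a directed cycle")
        if any(u >= self.n_nodes or v >= self.n_nodes for u, v in self.edges):
            raise ValueError("dag edge index out of range")


def default_dag_spec() -> DagSpec:
    """A 16-node DAG: the driver fans out to ten targets, four of which feed
    deeper targets (two of them as a collider pair), pinning edge directions."""
    edges = [(0, i) for i in range(1, 11)]
    edges += [(1, 11), (2, 11), (3, 12), (4, 13), (11, 14), (12, 15)]
    return DagSpec(n_nodes=16, edges=tuple(edges), root=0)


@dataclass
class SimConfig:
    n_studies: int = 8
    samples_per_group: tuple[int, int] = (8, 20)  # inclusive range per study
    n_genes: int = 1000
    # (parent size, list of child sizes) per module; the first parent is the
    # disease module, kept flat so its hub gene stays central
    module_spec: list[tuple[int, list[int]]] = field(
        default_factory=lambda: [(120, []), (100, [50, 30]), (80, [40, 20])]
    )
    frac_deg: float = 0.4
    effect_mean: float = 1.0
    effect_sd: float = 0.2
    # coherent = the disease module is dysregulated in one direction (down),
    # as in degenerating tissue; False draws a random sign per gene
    deg_sign_coherent: bool = True
    factor_loading: float = 0.7
    driver_loading: float = 0.98
    dag_coupling: float = 0.6  # extra signal carried from DAG parents to children
    noise_sd: float = 1.0  # residual sd for background genes (unit marginal)
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"sex": 0.2, "age": 0.01, "rin": 0.1}
    )
    probes_per_gene: tuple[float, float, float] = (0.5, 0.3, 0.2)  # P(1),P(2),P(3)
    probe_noise_sd: float = 0.3
    batch_sd: float = 1.0
    scale_jitter: float = 0.2
    severity_sd: float = 0.3
    stage_levels: int = 7
    dag_spec: DagSpec | None = field(default_factory=default_dag_spec)
    seed: int = 0

    def validate(self) -> None:
        if self.n_studies < 1 or self.n_genes < 1:
            raise ValueError("n_studies and n_genes must be positive")
        if not 0.0 <= self.frac_deg <= 1.0:
            raise ValueError("frac_deg must lie in [0, 1]")
        if not 0.0 <= self.factor_loading < 1.0:
            raise ValueError("factor_loading must lie in [0, 1)")
        total = sum(p for p, _ in self.module_spec)
        if total > self.n_genes:
            raise ValueError(
                f"module sizes sum to {total} > n_genes={self.n_genes}"
            )
        for p, children in self.module_spec:
            if sum(children) > p:
                raise ValueError("child module sizes exceed their parent")
        if self.dag_spec is not None:
            self.dag_spec.validate()
            if self.module_spec and self.dag_spec.n_nodes > self.module_spec[0][0]:
                raise ValueError("dag_spec larger than the disease module")


@dataclass
class SimTruth:
    """Ground truth the downstream analyses are expected to recover."""

    deg_genes: dict[str, float]  # gene -> signed true SMD
    module_assignment: dict[str, tuple[str, str | None]]  # gene -> (parent, child)
    dag_edges: list[tuple[str, str]]
    dag_cpts: dict[str, tuple[tuple[str, ...], np.ndarray]]  # node -> (parents, table)
    key_drivers: list[str]
    stage_score: dict[str, pd.Series]  # study_id -> per-sample ordinal stage
    covariates: dict[str, pd.DataFrame]
    probe_map: pd.Series
    genes: list[str]
    disease_module: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "deg_genes": self.deg_genes,
            "module_assignment": {g: list(v) for g, v in self.module_assignment.items()},
            "dag_edges": [list(e) for e in self.dag_edges],
            "key_drivers": self.key_drivers,
            "stage_score": {s: v.to_dict() for s, v in self.stage_score.items()},
            "disease_module": self.disease_module,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _module_layout(config: SimConfig, genes: list[str]):
    """Assign genes to parent/child modules; returns per-gene module path."""
    assignment: dict[str, tuple[str, str | None]] = {}
    cursor = 0
    for m, (psize, children) in enumerate(config.module_spec):
        pid = f"P{m + 1}"
        block = genes[cursor : cursor + psize]
        ccursor = 0
        for c, csize in enumerate(children):
            cid = f"{pid}.C{c + 1}"
            for g in block[ccursor : ccursor + csize]:
                assignment[g] = (pid, cid)
            ccursor += csize
        for g in block[ccursor:]:
            assignment[g] = (pid, None)
        cursor += psize
    return assignment, cursor


def _topo_order(spec: DagSpec) -> list[int]:
    import networkx as nx

    g = nx.DiGraph(spec.edges)
    g.add_nodes_from(range(spec.n_nodes))
    return list(nx.lexicographical_topological_sort(g))


def _build_cpts(config: SimConfig, node_names: list[str]):
    """Categorical conditional tables: 3 levels, noisy copy of the rounded
    parent mean with probability ``fidelity``, remainder split evenly."""
    spec = config.dag_spec
    f = spec.fidelity
    parents_of: dict[int, list[int]] = {i: [] for i in range(spec.n_nodes)}
    for u, v in spec.edges:
        parents_of[v].append(u)
    cpts: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
    for i in range(spec.n_nodes):
        pa = sorted(parents_of[i])
        if not pa:
            table = np.full(3, 1.0 / 3.0)
        else:
            shape = (3,) * len(pa) + (3,)
            table = np.empty(shape)
            for idx in np.ndindex(*(3,) * len(pa)):
                target = int(round(float(np.mean(idx))))
                row = np.full(3, (1.0 - f) / 2.0)
                row[target] = f
                table[idx] = row
        cpts[node_names[i]] = (tuple(node_names[j] for j in pa), table)
    return cpts


def generate_cohorts(config: SimConfig) -> tuple[list[ExpressionStudy], SimTruth]:
    """Generate ``config.n_studies`` cohorts plus the planted truth.

    Deterministic given ``config.seed``; all randomness flows through one
    :class:`numpy.random.Generator`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    assignment, n_module_genes = _module_layout(config, genes)

    disease_module = (
        [g for g, (p, _) in assignment.items() if p == "P1"] if config.module_spec else []
    )

    # planted DEG effects live in the disease module
    deg_genes: dict[str, float] = {}
    if disease_module and config.frac_deg > 0:
        n_deg = int(round(config.frac_deg * len(disease_module)))
        chosen = list(rng.choice(disease_module, size=n_deg, replace=False))
        driver = disease_module[0]
        if config.dag_spec is not None and driver not in chosen and n_deg > 0:
            chosen[0] = driver  # the driver is itself dysregulated
        for g in sorted(chosen):
            delta = rng.normal(config.effect_mean, config.effect_sd)
            if config.deg_sign_coherent:
                sign = -1.0
            else:
                sign = -1.0 if rng.random() < 0.5 else 1.0
            deg_genes[g] = sign * delta

    # per-gene factor loadings
    lam = config.factor_loading
    lam_p = np.zeros(config.n_genes)
    lam_c = np.zeros(config.n_genes)
    parent_ids = sorted({p for p, _ in assignment.values()})
    child_ids = sorted({c for _, c in assignment.values() if c is not None})
    for i, g in enumerate(genes):
        if g not in assignment:
            continue
        p, c = assignment[g]
        if c is None:
            lam_p[i] = lam
        else:
            lam_p[i] = lam * np.sqrt(0.6)
            lam_c[i] = lam * np.sqrt(0.4)
    key_drivers: list[str] = []
    if disease_module and config.dag_spec is not None:
        driver = disease_module[config.dag_spec.root]
        i = genes.index(driver)
        lam_p[i], lam_c[i] = config.driver_loading, 0.0
        key_drivers = [driver]
    resid_sd = np.sqrt(np.clip(1.0 - lam_p**2 - lam_c**2, 0.0, None))
    resid_sd[n_module_genes:] = config.noise_sd

    # probe layout is shared across studies (one platform map per gene here;
    # per-study maps would only add bookkeeping, not signal)
    n_probes = 1 + rng.choice(3, size=config.n_genes, p=np.r_[config.probes_per_gene])
    n_probes = np.minimum(n_probes, 3)
    probe_ids, probe_gene = [], []
    for g, k in zip(genes, n_probes):
        for j in range(k):
            probe_ids.append(f"{g}_at{j + 1}")
            probe_gene.append(g)
    probe_map = pd.Series(probe_gene, index=probe_ids, name="gene")

    deg_idx = np.array([genes.index(g) for g in deg_genes], dtype=int)
    deg_delta = np.array([deg_genes[g] for g in deg_genes])

    # ordinal stage thresholds: fixed, evenly spaced over the severity range
    stage_cuts = np.linspace(-0.3, 1.3, config.stage_levels - 1) if config.stage_levels > 1 else np.array([])

    studies: list[ExpressionStudy] = []
    stage_scores: dict[str, pd.Series] = {}
    covariate_frames: dict[str, pd.DataFrame] = {}
    lo, hi = config.samples_per_group
    for s in range(config.n_studies):
        sid = f"STUDY{s + 1}"
        n_case = int(rng.integers(lo, hi + 1))
        n_ctrl = int(rng.integers(lo, hi + 1))
        n = n_case + n_ctrl
        group = np.array(["case"] * n_case + ["control"] * n_ctrl)
        sample_ids = [f"{sid}_S{j + 1}" for j in range(n)]

        sex = rng.integers(0, 2, size=n)
        age = rng.normal(70.0, 8.0, size=n)
        rin = rng.normal(7.0, 1.0, size=n)
        severity = np.where(
            group == "case",
            rng.normal(1.0, config.severity_sd, size=n),
            rng.normal(0.0, config.severity_sd, size=n),
        )
        stage = np.searchsorted(stage_cuts, severity)

        f_parent = {p: rng.normal(size=n) for p in parent_ids}
        f_child = {c: rng.normal(size=n) for c in child_ids}
        eps = rng.normal(size=(config.n_genes, n))
        x = resid_sd[:, None] * eps
        for i, g in enumerate(genes[:n_module_genes]):
            p, c = assignment[g]
            x[i] += lam_p[i] * f_parent[p]
            if c is not None:
                x[i] += lam_c[i] * f_child[c]
        # regulatory footprint: DAG children inherit a standardized fraction
        # of their parents' signal (unit marginal variance preserved)
        if config.dag_spec is not None and disease_module:
            a = config.dag_coupling
            dag_parents: dict[int, list[int]] = {}
            for u, v in config.dag_spec.edges:
                dag_parents.setdefault(v, []).append(u)
            gidx = {g: genes.index(g) for g in disease_module[: config.dag_spec.n_nodes]}
            order = _topo_order(config.dag_spec)
            for node in order:
                if node not in dag_parents or a == 0.0:
                    continue
                rows = [gidx[disease_module[u]] for u in dag_parents[node]]
                parent_mean = x[rows].mean(axis=0)
                sd = parent_mean.std()
                if sd > 0:
                    parent_mean = parent_mean / sd
                i = gidx[disease_module[node]]
                mixed = np.sqrt(1.0 - a * a) * x[i] + a * parent_mean
                msd = mixed.std()
                x[i] = mixed / msd if msd > 0 else mixed
        if deg_idx.size:
            x[deg_idx] += deg_delta[:, None] * severity[None, :]
        cov_effect = (
            config.covariate_effects.get("sex", 0.0) * sex
            + config.covariate_effects.get("age", 0.0) * (age - 70.0)
            + config.covariate_effects.get("rin", 0.0) * (rin - 7.0)
        )
        x += cov_effect[None, :]

        scale = 1.0 + rng.uniform(-config.scale_jitter, config.scale_jitter)
        batch = rng.normal(0.0, config.batch_sd, size=config.n_genes)
        x = scale * x + batch[:, None] + 8.0  # platform intensity baseline (log2 scale)

        # expand genes to probes with independent probe noise
        probe_rows = np.repeat(np.arange(config.n_genes), n_probes)
        mat = x[probe_rows] + rng.normal(0.0, config.probe_noise_sd, size=(len(probe_ids), n))

        meta = pd.DataFrame(
            {
                "group": group,
                "sex": np.where(sex == 1, "M", "F"),
                "age": age,
                "rin": rin,
                "stage": stage,
            },
            index=sample_ids,
        )
        exprs = pd.DataFrame(mat, index=probe_ids, columns=sample_ids)
        studies.append(
            ExpressionStudy(
                exprs=exprs,
                sample_meta=meta,
                probe_map=probe_map.copy(),
                study_id=sid,
                log_scale=True,
            )
        )
        stage_scores[sid] = meta["stage"].copy()
        covariate_frames[sid] = meta[["sex", "age", "rin"]].copy()

    dag_edges: list[tuple[str, str]] = []
    dag_cpts: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
    if config.dag_spec is not None and disease_module:
        node_names = [disease_module[i] for i in range(config.dag_spec.n_nodes)]
        dag_edges = [
            (disease_module[u], disease_module[v]) for u, v in config.dag_spec.edges
        ]
        dag_cpts = _build_cpts(config, node_names)

    truth = SimTruth(
        deg_genes=deg_genes,
        module_assignment=assignment,
        dag_edges=dag_edges,
        dag_cpts=dag_cpts,
        key_drivers=key_drivers,
        stage_score=stage_scores,
        covariates=covariate_frames,
        probe_map=probe_map,
        genes=genes,
        disease_module=disease_module,
    )
    return studies, truth


def generate_gene_sets(
    truth: SimTruth,
    config: SimConfig,
    contamination: float = 0.0,
    n_gwas: int = 30,
    gwas_overlap: float = 0.5,
    n_cell_types: int = 3,
    cell_type_size: int = 25,
    seed: int | None = None,
) -> dict[str, set[str]]:
    """GMT-style catalog: module-aligned sets (optionally contaminated), a
    GWAS-like set overlapping the disease module, and disjoint cell-type sets.

    ``contamination`` is the exact fraction of each module-aligned set
    replaced by background genes.
    """
    rng = np.random.default_rng(config.seed + 104729 if seed is None else seed)
    module_genes: dict[str, list[str]] = {}
    for g, (p, c) in truth.module_assignment.items():
        module_genes.setdefault(p, []).append(g)
        if c is not None:
            module_genes.setdefault(c, []).append(g)
    background = sorted(set(truth.genes) - set(truth.module_assignment))

    catalog: dict[str, set[str]] = {}
    for mid in sorted(module_genes):
        members = sorted(module_genes[mid])
        n_swap = int(round(contamination * len(members)))
        if n_swap > 0:
            drop = rng.choice(len(members), size=n_swap, replace=False)
            keep = [m for i, m in enumerate(members) if i not in set(drop.tolist())]
            fill = rng.choice(background, size=n_swap, replace=False)
            members = keep + list(fill)
        catalog[f"SET_{mid}"] = set(members)

    if truth.disease_module:
        n_in = int(round(gwas_overlap * n_gwas))
        n_in = min(n_in, len(truth.disease_module))
        inside = rng.choice(truth.disease_module, size=n_in, replace=False)
        outside = rng.choice(background, size=n_gwas - n_in, replace=False)
        catalog["GWAS_LIKE"] = set(inside) | set(outside)

    pool = [g for g in background if g not in catalog.get("GWAS_LIKE", set())]
    rng.shuffle(pool)
    for t in range(n_cell_types):
        chunk = pool[t * cell_type_size : (t + 1) * cell_type_size]
        if chunk:
            catalog[f"CELLTYPE_{t + 1}"] = set(chunk)
    return catalog


def generate_tf_prior(
    truth: SimTruth,
    regulon_frac: float = 0.5,
    seed: int | None = None,
) -> pd.DataFrame:
    """TF->target prior table emulating a binding-site-derived regulon.

    Real TF-target catalogs (ChIP-based) list broad regulons: supersets of
    the causally active targets. The prior therefore contains every planted
    DAG edge plus, for the key-driver TF, a random ``regulon_frac`` of the
    disease module's genes. Deterministic given ``seed`` (defaults to a
    fixed offset so the table is reproducible from the truth alone).
    """
    pairs = list(truth.dag_edges)
    if truth.key_drivers and truth.disease_module:
        rng = np.random.default_rng(7919 if seed is None else seed)
        driver = truth.key_drivers[0]
        known = {t for tf, t in pairs if tf == driver} | {driver}
        pool = [g for g in truth.disease_module if g not in known]
        n_extra = int(round(regulon_frac * len(truth.disease_module))) - len(known) + 1
        if n_extra > 0 and pool:
            extra = rng.choice(pool, size=min(n_extra, len(pool)), replace=False)
            pairs += [(driver, g) for g in sorted(extra)]
    return pd.DataFrame(sorted(set(pairs)), columns=["tf", "target"])


def sample_dag_data(
    truth: SimTruth, n_samples: int, seed: int
) -> pd.DataFrame:
    """Ancestral sampling from the planted categorical DAG (3 levels).

    Returns a node x sample integer matrix. Deterministic given ``seed``.
    """
    import networkx as nx

    g = nx.DiGraph(truth.dag_edges)
    g.add_nodes_from(truth.dag_cpts)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("planted dag is cyclic")
    order = list(nx.lexicographical_topological_sort(g))
    rng = np.random.default_rng(seed)
    values: dict[str, np.ndarray] = {}
    for node in order:
        parents, table = truth.dag_cpts[node]
        if not parents:
            probs = np.tile(table, (n_samples, 1))
        else:
            idx = tuple(values[p] for p in parents)
            probs = table[idx]
        u = rng.random(n_samples)
        values[node] = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
    nodes = sorted(truth.dag_cpts)
    return pd.DataFrame(
        np.vstack([values[n] for n in nodes]).astype(np.int8),
        index=nodes,
        columns=[f"D{j + 1}" for j in range(n_samples)],
    )


def write_cohorts(
    studies: list[ExpressionStudy], truth: SimTruth, outdir: str | Path
) -> None:
    """Write each cohort as expression + metadata TSV, the probe map as a
    two-column TSV, and the truth object as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for st in studies:
        st.exprs.to_csv(outdir / f"{st.study_id}_exprs.tsv", sep="\t")
        st.sample_meta.to_csv(outdir / f"{st.study_id}_meta.tsv", sep="\t")
    truth.probe_map.rename_axis("probe").to_csv(outdir / "probe_map.tsv", sep="\t")
    truth.to_json(outdir / "truth.json")
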
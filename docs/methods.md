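# Methods

This note documents the models and procedures implemented in `nigranet`,
the parameters that matter, the synthetic data the tests run on, and the
numerical/design choices made where more than one defensible option exists.

## Scope and data model

The package targets the common situation in postmortem-brain transcriptomics
where several small case/control cohorts exist on heterogeneous platforms.
A cohort is an `ExpressionStudy`: a probe × sample intensity matrix (log2 or
linear, flagged), per-sample metadata (`group` ∈ {case, control}, covariates,
optionally an ordinal stage score), and a probe→gene map. Cohorts with fewer
than 5 samples in either arm are rejected (configurable gate).

## Preprocessing

* **Quantile normalization** maps each column onto the across-column mean of
  sorted values. Ties receive the mean of the reference values over their
  rank span (the common reference-distribution convention; the alternative —
  interpolated fractional ranks — differs only at tied values).
* **Covariate regression** replaces each gene by intercept + OLS residuals
  on the named covariates (categoricals expanded to indicators, columns
  mean-centered so the intercept is the gene's mean level and expression
  keeps its scale). The case/control label is never admitted as a covariate.
  Constant or missing covariates are dropped with a warning; rank-deficient
  designs are resolved by least squares. The operation is idempotent.
* **Probe collapse** keeps, per gene, the probe with the largest
  across-sample variance; ties break to the lexicographically smallest probe
  id so results are reproducible.
* **Z-score merging** standardizes each gene *within each study over both
  arms* (unbiased sd, n−1), then concatenates the requested arm's columns
  across studies. Standardizing over both arms is essential: per-arm
  standardization would erase the case/control difference itself. Genes not
  present in every study are dropped (the meta-analysis likewise requires a
  gene in all studies); constant genes are set to 0 with a warning.

## Meta-analysis

Per gene and study the effect is Hedges' g = J·(x̄_case − x̄_ctrl)/s_pooled
with J = 1 − 3/(4(n₁+n₂−2)−1) and sampling variance
v = (n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂)). Fixed-effect pooling uses weights 1/v;
Cochran's Q is referred to χ²(k−1), and when p_het < 0.05 the gene is
re-pooled with DerSimonian–Laird weights 1/(v+τ²),
τ² = max(0, (Q−(k−1))/(Σw − Σw²/Σw)). The two-sided p-value uses the normal
approximation pooled/se. DEGs require BH-FDR < 0.05 *and* |pooled SMD| > 0.5
jointly; direction is the sign of the pooled estimate. BH is applied across
all genes jointly, not per direction. The "mean SMD" gate is interpreted on
the pooled (inverse-variance) estimate; the unweighted per-study mean is
also emitted for users who prefer it. Stage association is Spearman's ρ
with midranks and the t approximation for p, BH across genes.

## Planar co-expression network

All gene pairs of the merged case matrix are screened by Pearson correlation
(two-sided t-transform p, BH across pairs, default FDR cut 0.05), sorted by
|ρ| descending with lexicographic tie-breaks, and inserted greedily subject
to graph planarity — a planar maximally filtered graph capped at 3n−6 edges.
Planarity is certified by the left-right test; because planarity holds iff
it holds on every biconnected component, the implementation keeps a bicomp
cache so each insertion tests only the touched component, rejects edges
inside an edge-maximal bicomp outright, and accepts bridges outright. The
result is exactly the sequential greedy construction (verified against a
naive reference in the tests).

### Module hierarchy

Connected components form the first scale. Each module is then split on its
induced subnetwork by Louvain clustering (edge weights = |ρ|) over an
ascending resolution scan (0.2–1.0); the *coarsest* partition is accepted
that (a) yields at least two children of ≥ 10 genes and (b) passes a
permutation gate, and accepted children recurse. Reported modules are those
of size > 50 (reporting only; recursion is unaffected).

The gate deserves explanation, because the two obvious designs both fail.
A degree-preserving rewiring null is wrong for planar-filtered graphs:
planar filtering itself imprints triangles and locality, so even the planar
skeleton of one homogeneous correlation block has far higher modularity
than its rewired version, and every spurious split would be certified.
Testing the partition against the correlations it was optimized on is
circular in the other direction: an optimized partition of pure noise
always looks cohesive in-sample. The implemented gate therefore separates
selection from inference by sample splitting. The samples are split once
into two halves; candidate partitions are derived from the *training*
half — Louvain on a complete graph with soft-thresholded weights |r|^6
(the co-expression convention; far more stable on half-sample estimates
than a hard edge cut) — and the gate statistic, the mean within-child minus
mean between-child pair |correlation| over **all** gene pairs of the
module, is evaluated on the *held-out* half against a child-label
permutation null (n_perm = 999 default, α = 0.05 Bonferroni-shared across
the resolution scan). For genes from one homogeneous block, held-out
within- and between-child pair strengths are exchangeable with respect to
a partition chosen on the other half, so no split is certified; genuine
nested structure transfers across halves and produces saturated p-values.
Without an expression matrix the gate falls back to the full-sample
correlations, or to the kept edge weights (adequate for toy graphs).

Louvain runs on integer-relabeled subgraphs built in sorted node order:
networkx's subgraph views and community aggregation otherwise iterate
string-keyed sets in process-dependent hash order, which silently breaks
reproducibility across interpreter runs.

### Hubs

Within each module, a gene is a hub iff its within-module degree strictly
exceeds the 95% quantile of the maximum degree over random graphs with the
module's node and edge counts (G(n,m), n_perm = 100). A degree-preserving
null is unusable here — rewiring a module's subgraph preserves every degree,
so no gene could ever exceed it; the edge-count-matched null reproduces the
expected behaviour (a star's center is its unique hub, a regular ring has
none).

## Consensus Bayesian network

Expression of the selected module's genes (the top module by DEG-signature
enrichment) is quantized per gene to three ordered levels by 1-d k-means
(levels sorted by cluster mean; quantile binning available). Structures are
sampled by Metropolis–Hastings over DAGs with add/delete/reverse edge moves,
enforcing acyclicity, a max-parents cap (default 3) and the TF prior as a
hard constraint (a target can never be proposed as parent of its TF) at
proposal time. The score is the BDeu Dirichlet-multinomial marginal
likelihood with equivalent sample size 1:

    Σ_j [lnΓ(a_j) − lnΓ(a_j+n_j)] + Σ_jk [lnΓ(a_jk+n_jk) − lnΓ(a_jk)],
    a_j = ess/q, a_jk = ess/(rq)

Acceptance is min(1, exp(Δscore)); proposal asymmetries from move
availability are not corrected, so the chains are a structure-search
ensemble rather than an exact posterior sampler — adequate because only the
consensus of many independently initialized chains is used downstream.
Chains start from a sparse random structure consistent with a random
topological order; the structure at the final step is the chain's vote.
Edges present in strictly more than 30% of chains form the consensus
(supports recorded), and the iterative de-loop removes, while any directed
cycle remains, the minimum-support edge among all edges inside nontrivial
strongly connected components (ties lexicographic on (source, target)).
Defaults: 1000 chains × 20k steps for production, 15 × 150k in the demo
configuration. Two scale choices matter. First, the pipeline models the
top-ranked module at *branch scale*: when the top-ranked module is a dense
core (the multiscale hierarchy deliberately surfaces DEG-dense cores), its
regulator typically sits in the enclosing branch, so the BN stage walks up
to the coarsest ancestor still below half the network before modeling.
Second, the modeled gene set is capped at the module's 60 most-connected
genes (`bn_max_genes`): the uniform pair-proposal kernel needs on the order
of n² steps per chain to visit every candidate edge a useful number of
times, and 150k steps at 60 genes gives each ordered pair ≈ 40 proposals.

## Key drivers and combined ranking

Downstream profiles are directed-BFS descendant sets (optionally bounded at
h layers); key drivers exceed mean + 2σ of all downstream counts (σ
multiplier configurable; the count distribution is heavily right-skewed, so
a 2σ rule isolates the tail). Candidates default to the intersection of BN
key drivers and co-expression hubs (union available). Each candidate's
two-layer neighborhood (undirected, center excluded; a directed-downstream
mode exists) is tested for DEG enrichment in each network with the whole
network as background; candidates are ranked per network by adjusted p
(ties: fold enrichment descending, then gene id) and combined as
G_j = Π_i (max_j r_ji + 1 − r_ji)/Σ_j r_ji. Larger G means better joint
rank; with n candidates the best possible per-network discriminant is
2/(n+1).

## Enrichment machinery

Over-representation uses the one-sided hypergeometric tail P(X ≥ k)
(scipy's survival function, exact in log space) with fold enrichment
(k/m)/(K/N); genes outside the declared background are ignored on both
sides, so results depend only on the stated universe. Module ranking uses
the union of module genes as background and scores each module by
Σ −log10(BH-adjusted p) over the signatures (a rank-product alternative is
provided); neighborhood annotation uses all network genes as background and
reports the smallest-adjusted-p term (ties to larger fold enrichment).

## Synthetic cohorts

The generator emulates the multi-cohort setting the pipeline is built for;
defaults are one realization of that setting, not tuned to any dataset:

* 8 cohorts of 8–20 samples/group (the demo uses 9–12, so the merged case
  arm lands near n ≈ 83, the scale of the emulated study design), gene
  expression Gaussian on the log2 scale with unit marginal variance before
  batch terms.
* Per-study additive per-gene batch offsets (sd 1.0) and a multiplicative
  scale jitter (±20%) — exactly the artifacts Z-score merging removes; 1–3
  probes per gene with independent probe noise (sd 0.3); sex/age/RIN
  covariate effects.
* Block co-expression from latent factors: parent-module loading 0.7
  (children of non-disease parents split it √0.6/√0.4 between parent and
  child factors). The disease module is flat, and its planted key driver
  *is* the module factor proxy (loading 0.98): every module gene is
  conditionally independent of the rest given the driver, which is what
  both hub detection and the BN are expected to discover.
* Planted case effects: a fraction (default 0.4) of disease-module genes
  receive δ·severity, |δ| ~ N(1.0, 0.2), where severity is N(1, 0.3²) in
  cases and N(0, 0.3²) in controls; the ordinal stage score is a fixed
  discretization of severity into 7 levels. Signs are coherent
  (downregulation) by default — the emulated disease module is a
  degenerating neuronal module — with a random-sign mode available
  (`deg_sign_coherent=False`). This ties differential expression to stage,
  makes the planted SMD ≈ δ up to a small (<5%) variance inflation, and —
  as in real data — introduces a severity-driven secondary correlation
  structure among affected genes that genuinely competes with the
  driver-centered structure.
* The regulatory DAG (default: a 16-node fan-out rooted at the driver, with
  collider nodes deeper down) leaves an expression footprint: each DAG
  child is √(1−a²)·(its module signal) + a·(standardized parent mean),
  re-standardized to unit variance, with coupling a = 0.6. Without this
  footprint the planted "regulation" would be invisible to any
  expression-based method at these sample sizes (the BDeu score prefers the
  empty graph when pairwise |ρ| ≲ 0.55 at n ≈ 80). The categorical tables
  used by `sample_dag_data` (noisy copy of the rounded parent mean,
  fidelity 0.85) are the separate, exact ground truth for the BN-recovery
  tests.
* The TF→target prior table emulates a binding-site-derived catalog: the
  planted DAG edges plus a broad regulon for the driver TF (a random half
  of the disease module). Real TF catalogs are supersets of the causally
  active targets, and the orientation information in that breadth is
  exactly what such priors contribute in practice.

What the generator does **not** emulate: hybridization physics, RNA-seq
counts, missing values, probe cross-hybridization, correlated covariates,
or confounding between batch and group. Passing tests therefore demonstrate
that each stage recovers the structure it targets under its stated
assumptions, not robustness to every artifact of real microarray archives.

## Numerical and degenerate-input conventions

Zero within-study sd → Z-score 0 with warning; zero pooled sd → gene
excluded from meta-analysis; constant genes dropped from the correlation
screen and the discretizer; modules of < 3 nodes have no hubs; < 5 nodes
refuse key-driver calls; empty queries are an error in enrichment while
zero overlap returns p = 1 exactly. All tie-breaks (probe selection, edge
ordering, de-loop, ranking) are lexicographic. Every stochastic routine
takes an explicit seed and is reproducible across processes; one caveat is
that BLAS reductions can differ across thread counts, so bit-level identity
is guaranteed within a fixed environment.

## Problem sizes used in the validation suite

The shipped tests and the acceptance script run at desk scale, chosen so
the full suite completes in minutes while every recovery property remains
measurable: 2000 genes × 8 cohorts for meta-analysis calibration; 5 × 80
gene blocks at n = 150 for module recovery (median ARI over 10 seeds);
a 10-node categorical DAG at n = 300 with 50 chains × 20k steps for BN
recovery; and 10 seeds of the 300-gene demo pipeline for end-to-end driver
recovery. The production defaults (1000 chains, genome-scale matrices) use
the same code paths.

## Known limitations

* The MCMC sampler's consensus is a frequency over local optima; it is not
  a calibrated posterior edge probability.
* Module detection's resolution scan is a finite grid; hierarchies finer
  than the grid's coarsest accepted level can be missed.
* The heterogeneity-gated model switch (fixed vs random) is the classical
  two-step procedure; it underestimates uncertainty relative to always
  fitting random effects.
* The generator's unit-variance Gaussian model makes quantile normalization
  nearly a no-op; its correctness is carried by exact unit tests instead.
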
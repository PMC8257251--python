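# Methods

This note documents the models and procedures `cafrank` implements,
the defaults and why they hold, what the synthetic-data generator does
and does not emulate, and the numerical conventions chosen where the
design was genuinely open.

## Preprocessing

The pipeline starts from an integer gene-by-sample count matrix with a
sample→group design of at least three groups with at least three
replicates each. The fixed order of operations is:

1. **Minimum-count filter**: keep genes with ≥ `min_count` (20) counts
   in ≥ `min_samples` (3) samples, counted across all samples rather
   than per group.
2. **Quantile normalization**: every column's value at rank *r* is
   replaced by the mean over columns of the *r*-th order statistic.
   Ties within a column receive the average of the reference values at
   the tied ranks — the dominant convention (as in limma's
   `normalizeQuantiles`), which makes the result invariant to the sort
   order of tied entries. A consequence worth knowing: a column with
   internal ties does not exactly preserve the common sorted multiset,
   since the averaged value replaces several distinct reference values.
3. **Flooring** at 20: values below the floor are raised to it. This
   deliberately damps fold-change inflation for lowly expressed genes
   and guarantees strictly positive values for CV and ratio
   computations.
4. **Protein-coding subset** (optional, when a coding-gene list is
   supplied), before the CV filter. An empty intersection raises,
   because it almost always signals a gene-ID-space mismatch rather
   than genuine disjointness.
5. **CV exclusion**: per group, CV = within-group sd (ddof = 1) /
   within-group mean per gene; the `ceil(0.01·G)` largest CVs of each
   group are flagged and the union of flagged genes removed. The union
   (rather than intersection) is the conservative reading of a
   per-group top-1% rule; `ceil` guarantees at least one gene per group
   is eligible. CV is computed on the floored matrix, i.e. the matrix
   as used downstream; provenance flags record the order.

Z-scoring for visualization uses the population sd; constant rows map
to all-zero rather than NaN so that clustering stays total.
Hierarchical clustering is average-linkage on Euclidean distances
(SciPy, deterministic smallest-index tie-break); PCA uses an SVD of the
per-feature-centered matrix with a deterministic sign convention.

## Signature selection and pruning

Fold change is the plain ratio of group means on the linear floored
scale — not a log-scale or variance-moderated statistic — because the
floor exists precisely to make this ratio robust. A gene enters a
signature when FC ≥ c (up) or FC ≤ 1/c (down); boundaries are
inclusive by default (configurable), a measure-zero choice on
continuous data. Cutoffs default to 2.0 for both macrometastasis
contrasts and 1.5 for MIF vs NLF, where expression shifts are subtler.
Raising a cutoff can only shrink a signature, and reversing a contrast
exactly swaps up and down; both properties are tested.

Connectivity pruning induces the PPI subgraph on a signature using
edges with confidence > 0.3, excluding text-mining evidence, and keeps
only connected components of ≥ 4 genes. Genes absent from the network
are dropped (isolated singletons). With `min_component=1` and
`min_conf=0` the operation is the identity on genes present in the
network.

## Over-representation and term consolidation

Per directional gene list and database, each term is intersected with
the post-preprocessing universe and skipped if empty or larger than
500 genes. The p-value is the exact hypergeometric upper tail
P(X ≥ |query ∩ term|); q-values are Benjamini–Hochberg within one
(database × comparison × direction) family, matching how per-run
enrichment platforms report them. Coverage uses the within-universe
term size as denominator. Records are kept at p < 0.01, q < 0.05 and
coverage > 3%.

Consolidation links two kept terms from *different* databases when
their overlap gene sets share ≥ 2 genes and the overlap coefficient
|A∩B| / min(|A|,|B|) exceeds 0.2 (Jaccard is available as an
alternative). Groups are the connected components of this graph;
components with < 3 terms or a single database are dropped. The group
score is the mean −log₁₀ q over member terms, negated for groups from
a downregulated list; q is floored at 1e-300 before the log. Group
labels default to the most frequent informative keyword across member
term names and can be overridden with a curated mapping.

A note on calibration: hypergeometric p-values are discrete, so for
small terms the attainable tail just below a threshold can be
materially smaller than the threshold. Calibration checks in the test
suite therefore use terms of a few hundred genes, where the null is
effectively continuous.

## GSEA

Ranking is the signal-to-noise ratio (μ₁−μ₂)/(σ₁+σ₂) on log₂ of the
normalized floored values, with each group's σ floored at 0.2·|μ|
(0.2 absolute when μ = 0) — the convention that prevents near-constant
genes from dominating. Ties are broken lexicographically by gene ID.

The enrichment score walks the ranked list, adding
|metric|^w / Σ_hits |metric|^w at set members (w = 1 by default) and
subtracting 1/(L−H) at non-members; ES is the signed maximum deviation
and the leading edge is the hit prefix (or suffix, for negative ES) up
to the extremum. With w = 0 the statistic is exactly the two-sample
Kolmogorov–Smirnov statistic between hit and miss ranks, which the
tests exploit as an oracle.

Because the stage groups hold only 3–4 replicates, significance uses
gene_set permutation (the phenotype-label null is underpowered and out
of scope): per set, 1000 random same-size gene sets give the null ES
distribution; NES divides ES by the mean |null ES| of matching sign;
the nominal p is the same-sign null tail fraction; and the FDR is the
canonical sign-stratified ratio of pooled normalized-null to observed
tail fractions, clipped to [0,1]. The null ES computation is
vectorized by evaluating the running sum only at its candidate
extrema — immediately after each hit (possible maximum) and
immediately before (possible minimum) — which the tests verify against
the full running sum. Defaults: sizes 5–500, significance at
FDR < 0.05 and |NES| > 2. Everything is deterministic given the seed.

## TF ranking

Eight parameters per (TF, comparison):

| parameter | source style | definition |
| --- | --- | --- |
| `string_degree` | PPI | signature genes adjacent to the TF at confidence > 0.2, all channels |
| `anat_direct` | anchored subnetwork | target genes adjacent to the TF in its subnetwork |
| `anat_cpl` | anchored subnetwork | mean unweighted hop distance from the TF to every reachable subnetwork node |
| `anat_centralization` | anchored subnetwork | Freeman degree centralization Σ(d_max−d_i)/((N−1)(N−2)) |
| `regnet_targets` | regulon | signature genes registered as TF targets |
| `var_n_direct` | relatedness | directly related signature genes |
| `var_mean_direct` | relatedness | mean score of those genes |
| `var_mean_indirect` | relatedness | mean score of indirectly related signature genes |

The anchored subnetwork fixes the pure shortest-path limit of
anchored-network inference: for each (TF, target) pair, the
minimum-cost path under edge cost −ln(confidence) — i.e. the
most-confident chain — on the confidence > 0.2 graph, with ties broken
by the lexicographically smallest node sequence for determinism; the
subnetwork is the union of these paths. The published anchored tools
optimize a shortest-path/Steiner trade-off; the trade-off parameter is
out of scope here, and the pure limit has the advantage of being
exactly checkable against all-pairs brute force. Characteristic path
length uses unweighted hops within the inferred subnetwork (matching
the common network-analyzer definition) over all reachable nodes,
directly and indirectly connected alike; unreachable targets are
recorded. Centralization is undefined (NaN) below three nodes.
Per-TF mode is the default; a combined-anchor subnetwork can be built
by passing several anchors.

Consolidation replaces the path length by its reciprocal (shorter
paths must rank higher; the map is monotone decreasing, which a
property test checks), imputes undefined values as 0 — the worst case
after the transform — and Z-scores each (comparison, parameter) across
TFs with the population sd; constant parameters become all-zero with a
warning. A TF's observations are its Z-scores over all cells (24 for
three comparisons); TFs are ranked by mean Z and compared by one-way
ANOVA plus Tukey's HSD (studentized range on pooled within-group
variance). When every observation is identical the ANOVA is
degenerate; by convention F = 0 and all p-values are 1. Candidate TFs
are an input list, not extracted automatically from enrichment output.
Relatedness summaries use all related signature genes; any top-k
restriction is a display concern, not a ranking one.

Note the two distinct PPI confidence cutoffs: signature pruning uses
> 0.3 with text-mining excluded, while both TF stages use > 0.2 with
all channels — they are separate defaults on purpose.

## Synthetic data

The generator emulates the targeted study design: three stage groups
(NLF/MIF/MAF) with 4/3/4 replicates, log-normal baseline expression
(median ≈ 150 counts, sdlog 1), negative-binomial counts with
var = μ + μ²·φ (φ = 0.1) scaled by log-normal library factors
(sdlog 0.2, renormalized to geometric mean 1). Per contrast, 40
stage-unique genes (half up, half down) have the numerator group's
mean scaled by 2^±2, and 20 shared genes ramp monotonically across
stages so they pass every contrast. The default problem size is 1000
genes — a scaled-down but structurally faithful cohort; the real data
regime (tens of thousands of genes) only changes runtime.

Knowledge networks: Erdős–Rényi background PPI (p = 0.004) plus a
denser coherence layer among planted signature genes (p = 0.02),
reflecting that co-regulated programs are enriched for interactions —
this is what gives connectivity pruning a meaningful retained core
(roughly half to three-quarters of a signature) instead of scattered
singletons. Confidences are U(0.15, 0.95); 20% of gene–gene edges are
labeled "textmining". One TF is designated central: it links to each
planted signature gene with probability 0.4 independently in each of
three channels (PPI edge, regulon edge, direct-relatedness row), while
the four decoys use 0.1. Direct relatedness rows score U(5, 30);
a random 30% of unlinked (gene, TF) pairs get indirect rows at
U(0, 5). TF–gene PPI edges are never text-mining, so channel exclusion
cannot erase the plant.

What the generator does **not** emulate: read-level artifacts
(alignment, duplication, GC bias), batch effects, correlated gene–gene
expression noise, fibroblast subpopulation heterogeneity, and
realistic gene-set topologies. Passing tests therefore demonstrate
correctness of the computational chain and its ability to recover a
planted signal under the stated noise model — not performance on any
particular real dataset.

## Problem sizes and determinism

Simulation-based checks use 100 independent seeds at the generator's
default size (1000 genes) for TF-ranking recovery, 100 seeds at 1000
GSEA permutations for planted-set detection, and 1000 replicate null
queries for ORA calibration; these sizes give the binomial margins the
checks assert while keeping the suite quick. All randomness flows
through a single integer seed per run (`numpy.random.default_rng`);
two runs with the same config and seed produce byte-identical output
files, enforced by a config-hash manifest that refuses to overwrite
results from a different configuration.

## Known limitations

- The anchored subnetwork is the shortest-path limit, not the full
  Steiner-tree trade-off of the published tools.
- BH q-values are per (database × comparison × direction) family;
  a global correction across databases is not offered.
- Group labeling of consolidated terms is a keyword heuristic; curated
  labels should be supplied for publication-grade output.
- Fold-change selection carries no replicate-level significance test,
  by design; it inherits the robustness (and the limits) of the
  floor-and-ratio scheme.
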
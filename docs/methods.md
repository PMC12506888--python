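# Methods

This note documents the statistical model behind `knowclust`, the choices
made where the design was genuinely open, and what the synthetic benchmarks
do and do not demonstrate.

## The model

The method treats cell-type discovery as model selection over partitions.
For a candidate partition of the query cells into k clusters, two signals
are combined multiplicatively:

- **Knowledge agreement p_k.** Each cluster's pseudo-bulk profile (mean
  log-normalized expression) is Spearman-correlated with every reference
  type over that type's most informative genes; the best-match correlations
  ρᵢ, weighted by gene-set coverage wᵢ, are pooled through the
  variance-stabilizing Fisher transform, z̄ = Σ wᵢ·atanh(ρᵢ)/Σ wᵢ, and
  mapped back: p_k = tanh(z̄). Pseudo-bulk aggregation suppresses dropout
  noise, and rank correlation makes the comparison robust to monotone
  platform effects between reference and query.
- **Explained variance BSS/TSS.** The fraction of variance a partition
  explains, computed in the representation that is clustered at that k:
  the row-normalized matrix of the first k eigenvectors of the symmetric
  normalized graph Laplacian. This point matters: in any *fixed* space the
  ratio is non-decreasing in k, so it cannot select a cluster number — the
  score would always favor k_max. In the k-dimensional spectral embedding,
  however, the ratio peaks at the eigengap: below the natural component
  count the eigenvector subspace merges groups, above it the extra
  eigenvectors inject continuous within-cluster directions that k-means
  cannot explain. (The standalone `bss_tss` function is a plain
  between/total sum-of-squares ratio in whatever space it is given.)

The selected k maximizes score = (BSS/TSS)·p_k over k = 2 … k_max, among
partitions whose smallest cluster has at least `min_cells` cells; exact ties
break toward smaller k.

Two details keep p_k informative. Correlations are clamped to |ρ| ≤ 1−1e−7
before atanh. More importantly, each type's matching gene set is the top
`top_gene_fraction` (default 10%) of the type's ranking of the **whole
knowledgebase union gene list**, not of its own 50-gene identity list: with
a 5-type knowledgebase this gives 25 genes per set. Spearman over 5 genes
takes only a handful of distinct values and saturates at ρ = 1 for almost
any plausible cluster, which collapses p_k to a constant; 25+ genes give the
score usable resolution. The printed weighted-Fisher form z = w·atanh(ρ) is
used; the algebraically different variant atanh(w·ρ) is available via
`RunConfig.fisher_variant` for comparison.

## Recursive refinement and the split test

Each initial cluster is refined recursively: its cells are re-embedded on
the stacked representation [global latent | the cluster's own normalized,
re-selected feature block], re-swept over k, and the best valid local
partition is either accepted or the cluster becomes a leaf. Feature
selection is *repeated inside each node*, so genes that vary only within a
cluster (e.g. markers of a rare subtype that are invisible to global
variance ranking) re-enter the representation.

The stopping rule is the method's most delicate part, because the natural
candidates are biased. Comparing a child's best-match correlation to the
parent's is biased in both directions: fragments of a homogeneous cluster
differ from their parent only by sampling noise (a coin flip), while a small
genuine subpopulation *loses* to a big parent because the Spearman estimate
attenuates with fewer cells. The implemented rule removes the size
confounder with a permutation null: for each child, the alignment of
size-matched random subsets of the parent with the child's matched type is
measured (`split_null_draws` = 15 draws, full union gene set), and the split
is accepted when some child exceeds its null by at least `split_z` = 1.5
null standard deviations. Fragments of a homogeneous cluster behave exactly
like random subsets — across 100 instrumented fragment splits their z never
exceeded 0.9 — while genuinely distinct subpopulations concentrate cells the
random subsets dilute and reach z ≥ 2 routinely; the default threshold sits
between the two observed distributions. The simpler aggregate rule
(children's pooled p_k must beat the parent's correlation) is kept behind
`RunConfig.split_rule = "aggregate"`.

Per-node autoencoders and k-means are seeded deterministically from the run
seed, node depth and traversal ordinal, so a run is bit-reproducible.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_identity_genes` | 50 | identity genes per reference type |
| `hvg_fraction` | 0.05 | fraction of top-variance genes kept |
| `top_gene_fraction` | 0.10 | fraction of the union ranking used for matching |
| `k_max` | 20 | sweep ceiling (further capped by n/min_cells) |
| `min_cells` | 30 | smallest admissible cluster |
| `hidden_widths`, `latent_dim` | (64,), 16 | autoencoder encoder widths |
| `activation` | tanh | autoencoder nonlinearity (`relu`, `identity` available) |
| `epochs`, `batch_size`, `learning_rate` | 50, 64, 1e-3 | Adam training |
| `n_neighbors` | 12 | kNN graph degree (locally scaled Gaussian weights) |
| `split_z`, `split_null_draws` | 1.5, 15 | split-acceptance permutation test |
| `include_kb_genes` | on | add knowledgebase genes to the feature space |
| `unassigned_threshold` | off | flag clusters with ρ below it as unassigned |

Autoencoder defaults were chosen for robustness at desk scale. A tanh (or
linear) bottleneck preserves low-variance structure: on an 8:1 imbalanced
benchmark a ReLU network recovered only 5–7 of 10 types in its latent space
versus 9–10 for tanh, which behaves closer to a principal-subspace
autoencoder. Fifty epochs suffice for the reconstruction loss to flatten;
several-fold longer training starts to memorize sampling noise and degrades
the downstream clustering. `include_kb_genes` exists for the same reason at
the feature level: a 25-cell type among 1,125 cells contributes too little
global variance for its markers to survive top-5% selection, but the
reference-derived identity genes keep it visible.

## Synthetic data

The generator emulates the statistical structure the method assumes:
distinct pseudo-bulk signatures per type under realistic sparsity. Gene
baselines are log-normal (median 1.5 counts, σ_log = 0.8); counts are
negative-binomial (dispersion 0.3, variance μ + 0.3μ²) with an extra dropout
step whose probability decays with expression, plus per-cell log-normal
library-size factors. Each type's disjoint marker genes are up-regulated by
a per-(gene,type) log-normal fold change (log₂ mean = `log_fold_change`,
log₂ sd = half of it). The heterogeneous factor is essential: a flat
multiplicative boost preserves the between-gene ordering shared by all
types, so every cluster would rank-correlate near 1 with every reference
type and knowledge guidance would be vacuous by construction; independent
per-type factors give each type its own marker ordering, as real marker
panels have. At `log_fold_change = 0` the factor is exactly 1 and no signal
exists. Hierarchical datasets add strong shared coarse markers
(log₂FC = 2) and weaker disjoint subtype markers (log₂FC = 1.5 — below ~1
the subtype signal is unrecoverable even by an oracle probe, so the fixture
would not exercise recursion). ADT counts are negative-binomial around a
higher baseline (20) with per-type marker proteins.

What passing these benchmarks shows: the score surface selects the planted
cluster number, the recursion deepens exactly as far as the knowledgebase
resolves, and the pipeline is robust to 8:1 imbalance and to an RNA-only
knowledgebase on bimodal data. What it does not show: robustness to batch
effects, doublets, ambient RNA, continuous differentiation trajectories, or
reference/query platform mismatches — none of which the generator models.

## Benchmark designs and sizes

The seeded scenarios (in `knowclust.benchmarks`, shared by the test suite
and `scripts/acceptance.py`) use: balanced — 5 types × 400 cells, 2,000
genes, split half/half into reference and query (200 query cells per type);
nested — 2 coarse × 2 subtypes × 300 cells (150 query cells per subtype),
knowledgebase built at subtype or coarse resolution; imbalanced — 10 types
× 450 cells, query subsampled to 5 major types of 200 and 5 minor types of
25 cells (8:1) with `min_cells = 20`; multimodal — the balanced design plus
30 ADT proteins, knowledgebase from RNA only. Ten seeds each.

## Numerical conventions and degenerate inputs

- Spearman of a constant vector is defined as 0 with a degenerate flag;
  matching requires ≥ 3 intersecting genes, otherwise the cluster is
  `unassigned` with zero weight. If every cluster is unassigned, p_k = 0.
- A coefficient of variation with zero mean counts as +∞ (worst stability);
  stability ranks use average ranks for ties; identity-gene ties at the
  cutoff break by ascending gene name.
- Standardization maps constant features to zero columns; CLR centers every
  feature exactly; log-normalization rejects zero-library cells by id.
- kNN bandwidths σᵢ (distance to the ⌈n_neighbors/2⌉-th neighbour) are
  floored at machine-epsilon scale of the median pairwise distance, so
  duplicate points cannot produce zero bandwidth.
- BSS/TSS is 0 when all points coincide; the ARI denominator degenerates
  only when both labelings are trivial, where identical partitions score 1
  and anything else 0; min-max scaling of a constant vector returns 0.5.
- MTX indices are 1-based on disk, 0-based in memory; dense readers accept
  both orientations and always return cells × features.

## Known limitations

- Annotation is cluster-level by design; no per-cell label transfer.
- A query type absent from the knowledgebase is absorbed into whichever
  cluster structure the data supports and flagged only through its low
  correlation (use `unassigned_threshold`).
- Types with fewer than `min_cells` query cells are unrecoverable by
  construction; with 25-cell minor types and `min_cells = 20` the margin is
  five cells, and a seed occasionally loses a minor type to boundary
  scatter at the initial partition.
- The global partition is not re-scored after recursion; refinement is
  local to each node.
- Affinity matrices are dense (n × n); the implementation targets
  desk-scale inputs (thousands of cells), not atlas-scale millions.
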
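# knowclust

Knowledge-guided clustering and cell-type number estimation for single-cell
omics data.

Unsupervised clustering of single-cell RNA-seq (and multimodal CITE-seq /
gene-activity) data leaves two hard questions to the analyst: *how many
clusters are really in the data*, and *what are they*. `knowclust` answers
both jointly by leaning on prior knowledge: a **knowledgebase** of reference
cell types — per type, a ranked list of *cell identity genes* (genes stably
and uniquely expressed in that type) and a pseudo-bulk expression profile —
guides the choice of the cluster number and annotates every cluster with its
closest reference type. It is aimed at analysts who have a labeled reference
(an atlas, a previous experiment, or curated marker sets) and want clustering
of a new query dataset that is both statistically coherent and biologically
interpretable.

## Method

1. **Knowledgebase construction.** From a labeled reference count matrix,
   each gene g receives a differential-stability score per type t, combining
   the fraction of expressing cells z₍g,t₎ and the coefficient of variation
   cv₍g,t₎ (both converted to within-type fractional ranks and contrasted
   against the other types). The top 50 genes per type are its identity
   genes; per-type profiles are mean log-normalized expression over the union
   of all identity genes. A one-vs-rest Wilcoxon alternative
   (Bonferroni-corrected p < .05) and fully manual gene sets are also
   supported.
2. **Embedding.** The query is normalized per modality (RNA/activity:
   library-size log-normalization; ADT: CLR across cells), restricted to the
   top 5% highly variable genes plus the knowledgebase genes, standardized,
   concatenated across modalities and compressed by a small autoencoder
   (tanh MLP trained with Adam on MSE). A locally scaled symmetric kNN
   affinity graph is built on the latent coordinates.
3. **Cluster-number estimation.** For k = 2 … K (default 20) the affinity
   graph is partitioned by normalized spectral clustering. Each cluster Cᵢ
   gets a pseudo-bulk profile, Spearman-matched against every reference type
   over the type's top 10% most stably expressed genes:
   ρᵢⱼ = 1 − 6Σd²/(G(G²−1)). Best-match correlations are combined by the
   weighted Fisher transform, z̄ = Σ wᵢ·atanh(ρᵢ) / Σ wᵢ with
   wᵢ = |intersection|/|gene set|, and mapped back to p_k = tanh(z̄). The
   selected k maximizes the **clustering score** = (BSS/TSS) · p_k, the
   explained-variance ratio of the partition times its knowledge agreement.
4. **Recursive refinement.** Each cluster is re-embedded on the *stacked*
   representation [latent | its own re-selected input block] and re-swept.
   A split is accepted only when every child keeps at least `min_cells`
   cells (default 30) and at least one child aligns with its matched
   reference identity significantly better than size-matched random subsets
   of the parent — so clusters split exactly as far as the knowledgebase
   can tell subpopulations apart. Final clusters are annotated with their
   best-matching type and correlation; low-correlation clusters can be
   flagged `unassigned`.

Evaluation utilities implement the adjusted Rand index (pair-counting
contingency formula), the absolute deviation ratio ADR = |c − ĉ|/c, min-max
scaling, and the benchmark subsampling designs (balanced, imbalanced
major/minor, fractional). A seeded synthetic-data module generates
negative-binomial, dropout-inflated datasets with planted markers — flat,
hierarchical (coarse types with subtypes) and bimodal RNA+ADT — so the whole
pipeline is testable without downloads.

## Worked example

```python
import knowclust as kc

# simulate a 5-type dataset and hold out half as a labeled reference
spec = kc.SimulationSpec(n_types=5, cells_per_type=400, n_genes=2000, seed=1)
ds = kc.simulate_counts(spec)
ref, query = kc.split_reference_query(ds, query_fraction=0.5, seed=1)

kb = kc.build_knowledgebase(ref.rna, ref.labels, method="stability", n_top=50)
model = kc.KnowledgeGuidedClustering(query.rna, kb, config=kc.RunConfig(seed=1))
res = model.fit()
print(res.summary())
print("ARI vs truth:", round(kc.ari(query.labels, res.labels), 4))
```

prints

```
Knowledge-guided clustering results
===================================
cells:           1000
final clusters:  5
reference types: 5 (stability)

cluster   size      rho  genes  matched type
      0    201   0.9877     25  type_2
      1    200   0.9962     25  type_0
      2    199   0.9738     25  type_1
      3    200   0.9846     25  type_3
      4    200   0.9854     25  type_4

ARI vs truth: 0.99
```

The model recovers the five planted types (1,000 query cells), annotates each
cluster with the correct reference type, and reports the Spearman correlation
of each cluster's pseudo-bulk profile with that type over the 25 matching
genes; `res.score_trace` holds the per-k score table behind the selection and
`res.annotate(threshold=0.3)` yields the per-cell result table. The same
workflow is available from the shell:

```sh
knowclust simulate --spec sim.yaml --out data/
knowclust build-kb --expr ref.tsv --labels labels.tsv --out kb/
knowclust --seed 1 cluster --rna query.tsv --kb kb/ --out out/
knowclust evaluate --pred out/pred.tsv --truth truth.tsv --out metrics.tsv
```

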
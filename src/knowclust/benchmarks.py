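"""Seeded benchmark scenarios: simulate, build the knowledgebase from a
held-out reference half, cluster the query, and score against the truth.

These mirror the evaluation designs the method is assessed under: balanced
multi-type queries, nested (coarse/fine) populations probing the recursion,
major/minor imbalance, and bimodal RNA+ADT queries with an RNA-only
knowledgebase.
"""

from __future__ import annotations

from dataclasses import dataclass

from .containers import RunConfig
from .kb import build_knowledgebase
from .metrics import adr, ari, imbalanced_subsample
from .model import ClusteringResults, cluster_query
from .simulate import (
    AdtSpec, HierarchySpec, SimulationSpec, simulate_counts, simulate_hierarchical,
    split_reference_query,
)


@dataclass
class ScenarioOutcome:
    seed: int
    truth_k: int
    n_clusters: int
    ari: float
    adr: float
    result: ClusteringResults
    truth_labels: list[str]


def _outcome(seed, truth_labels, result) -> ScenarioOutcome:
    truth_k = len(set(truth_labels))
    return ScenarioOutcome(
        seed, truth_k, result.n_clusters,
        ari(truth_labels, result.labels), adr(truth_k, result.n_clusters),
        result, list(truth_labels),
    )


def balanced_scenario(seed: int, n_types: int = 5, cells_per_type: int = 400,
                      n_genes: int = 2000) -> ScenarioOutcome:
    """Balanced query of ``n_types`` with a matching stability knowledgebase
    built from the held-out half (200 query cells per type at defaults)."""
    spec = SimulationSpec(n_types=n_types, cells_per_type=cells_per_type,
                          n_genes=n_genes, seed=seed)
    ds = simulate_counts(spec)
    ref, query = split_reference_query(ds, 0.5, seed=seed)
    kb = build_knowledgebase(ref.rna, ref.labels, method="stability", n_top=50)
    result = cluster_query(query.rna, kb, config=RunConfig(seed=seed))
    return _outcome(seed, query.labels, result)


def nested_scenario(seed: int, kb_level: str = "fine") -> ScenarioOutcome:
    """2 coarse x 2 subtype query; the kb is built at ``fine`` (subtype) or
    ``coarse`` resolution, probing knowledge-guided recursion depth."""
    spec = SimulationSpec(
        n_types=4, cells_per_type=300, n_genes=2000, seed=seed,
        hierarchy=HierarchySpec(n_coarse=2, subtypes_per_coarse=2),
    )
    ds = simulate_hierarchical(spec)
    ref, query = split_reference_query(ds, 0.5, seed=seed)
    ref_labels = ref.labels if kb_level == "fine" else ref.coarse_labels
    truth = query.labels if kb_level == "fine" else query.coarse_labels
    kb = build_knowledgebase(ref.rna, ref_labels, method="stability", n_top=50)
    result = cluster_query(query.rna, kb, config=RunConfig(seed=seed))
    return _outcome(seed, truth, result)


def imbalanced_scenario(seed: int, ratio: int = 8, n_major_cells: int = 200,
                        min_cells: int = 20) -> ScenarioOutcome:
    """10-type query subsampled to 5 major / 5 minor types at ``ratio``:1."""
    spec = SimulationSpec(n_types=10, cells_per_type=450, n_genes=2000, seed=seed)
    ds = simulate_counts(spec)
    ref, query = split_reference_query(ds, 0.5, seed=seed)
    kb = build_knowledgebase(ref.rna, ref.labels, method="stability", n_top=50)
    qx, ql = imbalanced_subsample(query.rna, query.labels,
                                  n_major_cells=n_major_cells, ratio=ratio, seed=seed)
    result = cluster_query(qx, kb, config=RunConfig(seed=seed, min_cells=min_cells))
    return _outcome(seed, ql, result)


def multimodal_scenario(seed: int) -> ScenarioOutcome:
    """RNA+ADT bimodal query clustered with an RNA-only knowledgebase."""
    spec = SimulationSpec(n_types=5, cells_per_type=400, n_genes=2000,
                          adt=AdtSpec(), seed=seed)
    ds = simulate_counts(spec)
    ref, query = split_reference_query(ds, 0.5, seed=seed)
    kb = build_knowledgebase(ref.rna, ref.labels, method="stability", n_top=50)
    result = cluster_query(query.rna, kb, config=RunConfig(seed=seed), adt=query.adt)
    return _outcome(seed, query.labels, result)
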
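"""Seeded synthetic single-cell datasets with known types and planted markers.

Counts are negative-binomial around log-normally distributed gene baselines,
with marker genes up-shifted by a fold change within their own type and an
extra dropout step whose probability decreases with expression level — the
zero-inflation that the differential-stability statistic relies on.  All
randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix, KnowclustError


@dataclass
class HierarchySpec:
    n_coarse: int = 2
    subtypes_per_coarse: int = 2
    sub_effect: float = 1.5  # log2 fold change of subtype markers (< coarse effect)


@dataclass
class AdtSpec:
    n_proteins: int = 30
    protein_effect: float = 2.0  # log2 fold change of per-type marker proteins
    base_mean: float = 20.0


@dataclass
class SimulationSpec:
    """Generative settings for one synthetic dataset.

    Defaults mirror the benchmark design the method is evaluated under:
    balanced types of 200 cells, 2,000 genes, 20 disjoint marker genes per
    type at a log2 fold change of 2 (4-fold), negative-binomial dispersion
    0.3 and a baseline mean of 1.5 counts.
    """

    n_types: int = 5
    cells_per_type: int = 200
    n_genes: int = 2000
    markers_per_type: int = 20
    log_fold_change: float = 2.0
    nb_dispersion: float = 0.3
    base_mean: float = 1.5
    base_log_sigma: float = 0.8
    dropout_logit_slope: float = 1.0
    library_log_sigma: float = 0.3
    hierarchy: HierarchySpec | None = None
    adt: AdtSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hierarchy is not None:
            h = self.hierarchy
            n_fine = h.n_coarse * h.subtypes_per_coarse
            budget = (h.n_coarse + n_fine) * self.markers_per_type
        else:
            budget = self.markers_per_type * self.n_types
        if budget > self.n_genes:
            raise KnowclustError(
                f"marker budget {budget} exceeds {self.n_genes} genes"
            )
        for name in ("n_types", "cells_per_type", "n_genes", "markers_per_type"):
            if getattr(self, name) < 1:
                raise KnowclustError(f"{name} must be >= 1")
        if self.log_fold_change < 0:
            raise KnowclustError("log_fold_change must be >= 0")


@dataclass
class SimulatedDataset:
    rna: ExpressionMatrix
    labels: list[str]
    markers: dict[str, list[str]]
    adt: ExpressionMatrix | None = None
    coarse_labels: list[str] | None = None
    protein_markers: dict[str, list[str]] | None = None
    # realized fold change per planted marker gene, aligned to markers[t]
    marker_factors: dict[str, np.ndarray] | None = None


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2."""
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _dropout(rng: np.random.Generator, counts: np.ndarray, mean: np.ndarray,
             slope: float) -> np.ndarray:
    if slope <= 0:
        return counts
    p_drop = 1.0 / (1.0 + np.exp(slope * np.log1p(mean)))
    keep = rng.random(counts.shape) >= p_drop
    return counts * keep


def _sample_counts(rng, cell_means, dispersion, slope, lib_sigma):
    counts = _nb_draw(rng, cell_means, dispersion)
    counts = _dropout(rng, counts, cell_means, slope)
    return counts.astype(float)


def _de_factor(rng: np.random.Generator, log_fold_change: float, size: int) -> np.ndarray:
    """Per-(gene, type) marker up-regulation factor.

    Log2 fold changes are heterogeneous across marker genes
    (sd = log_fold_change / 2), so a type's marker ordering is its own and
    not simply the shared baseline ordering scaled up; at
    log_fold_change = 0 the factor is exactly 1 and no signal is planted.
    """
    if log_fold_change == 0:
        return np.ones(size)
    lfc = rng.normal(log_fold_change, log_fold_change / 2.0, size)
    return 2.0 ** lfc


def _gene_names(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(n)]


def _cell_ids(n: int) -> list[str]:
    return [f"cell_{i:05d}" for i in range(n)]


def simulate_counts(spec: SimulationSpec) -> SimulatedDataset:
    """Flat multi-type RNA counts with disjoint planted marker genes."""
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)
    base = np.exp(rng.normal(np.log(spec.base_mean), spec.base_log_sigma, spec.n_genes))
    types = [f"type_{i}" for i in range(spec.n_types)]
    marker_idx = {
        t: np.arange(i * spec.markers_per_type, (i + 1) * spec.markers_per_type)
        for i, t in enumerate(types)
    }
    factors: dict[str, np.ndarray] = {}
    labels, blocks = [], []
    for t in types:
        mu = base.copy()
        factors[t] = _de_factor(rng, spec.log_fold_change, spec.markers_per_type)
        mu[marker_idx[t]] = base[marker_idx[t]] * factors[t]
        scale = np.exp(rng.normal(0.0, spec.library_log_sigma, (spec.cells_per_type, 1)))
        cell_means = mu[None, :] * scale
        blocks.append(
            _sample_counts(rng, cell_means, spec.nb_dispersion,
                           spec.dropout_logit_slope, spec.library_log_sigma)
        )
        labels.extend([t] * spec.cells_per_type)
    values = np.vstack(blocks)
    rna = ExpressionMatrix(values, _cell_ids(values.shape[0]), genes, "RNA", "counts")
    markers = {t: [genes[i] for i in idx] for t, idx in marker_idx.items()}
    ds = SimulatedDataset(rna, labels, markers, marker_factors=factors)
    if spec.adt is not None:
        _add_adt(ds, spec, rng)
    return ds


def simulate_hierarchical(spec: SimulationSpec) -> SimulatedDataset:
    """Nested types: strong shared coarse markers, weaker disjoint subtype markers."""
    if spec.hierarchy is None:
        raise KnowclustError("simulate_hierarchical needs spec.hierarchy")
    h = spec.hierarchy
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)
    base = np.exp(rng.normal(np.log(spec.base_mean), spec.base_log_sigma, spec.n_genes))
    m = spec.markers_per_type
    coarse_names = [f"coarse_{c}" for c in range(h.n_coarse)]
    fine_names, markers, coarse_markers = [], {}, {}
    cursor = 0
    for c, cname in enumerate(coarse_names):
        coarse_markers[cname] = np.arange(cursor, cursor + m)
        cursor += m
    for c, cname in enumerate(coarse_names):
        for s in range(h.subtypes_per_coarse):
            fname = f"{cname}_sub{s}"
            fine_names.append(fname)
            markers[fname] = np.arange(cursor, cursor + m)
            cursor += m
    # coarse markers share one on-state across a coarse type's subtypes
    coarse_on = {
        cname: base[coarse_markers[cname]]
        * _de_factor(rng, spec.log_fold_change, m)
        for cname in coarse_names
    }
    labels, coarse_labels, blocks = [], [], []
    for cname in coarse_names:
        for fname in (f for f in fine_names if f.startswith(cname + "_")):
            mu = base.copy()
            mu[coarse_markers[cname]] = coarse_on[cname]
            mu[markers[fname]] = base[markers[fname]] * _de_factor(rng, h.sub_effect, m)
            scale = np.exp(rng.normal(0.0, spec.library_log_sigma,
                                      (spec.cells_per_type, 1)))
            blocks.append(
                _sample_counts(rng, mu[None, :] * scale, spec.nb_dispersion,
                               spec.dropout_logit_slope, spec.library_log_sigma)
            )
            labels.extend([fname] * spec.cells_per_type)
            coarse_labels.extend([cname] * spec.cells_per_type)
    values = np.vstack(blocks)
    rna = ExpressionMatrix(values, _cell_ids(values.shape[0]), genes, "RNA", "counts")
    marker_names = {
        t: [genes[i] for i in np.concatenate([coarse_markers[t.split("_sub")[0]], idx])]
        for t, idx in markers.items()
    }
    ds = SimulatedDataset(rna, labels, marker_names, coarse_labels=coarse_labels)
    if spec.adt is not None:
        _add_adt(ds, spec, rng)
    return ds


def simulate_multimodal(spec: SimulationSpec) -> SimulatedDataset:
    """RNA + ADT over the same cells; ADT carries its own per-type protein signal."""
    if spec.adt is None:
        spec_adt = SimulationSpec(**{**spec.__dict__, "adt": AdtSpec()})
        return simulate_counts(spec_adt)
    return simulate_counts(spec)


def _add_adt(ds: SimulatedDataset, spec: SimulationSpec, rng: np.random.Generator) -> None:
    a = spec.adt
    types = sorted(set(ds.labels))
    per_type = max(1, a.n_proteins // max(len(types), 1))
    prot_names = [f"p{i:03d}" for i in range(a.n_proteins)]
    base = np.exp(rng.normal(np.log(a.base_mean), 0.5, a.n_proteins))
    prot_markers = {}
    lab = np.asarray(ds.labels)
    values = np.zeros((len(ds.labels), a.n_proteins))
    for i, t in enumerate(types):
        idx = np.arange(i * per_type, min((i + 1) * per_type, a.n_proteins))
        prot_markers[t] = [prot_names[j] for j in idx]
        mu = base.copy()
        mu[idx] = base[idx] * _de_factor(rng, a.protein_effect, idx.size)
        mask = lab == t
        values[mask] = _nb_draw(rng, np.broadcast_to(mu, (mask.sum(), a.n_proteins)),
                                spec.nb_dispersion).astype(float)
    ds.adt = ExpressionMatrix(values, list(ds.rna.cell_ids), prot_names, "ADT", "counts")
    ds.protein_markers = prot_markers


def split_reference_query(
    ds: SimulatedDataset, query_fraction: float = 0.5, seed: int = 0
) -> tuple[SimulatedDataset, SimulatedDataset]:
    """Per-type stratified split into a labeled reference and a query half."""
    if not (0 < query_fraction < 1):
        raise KnowclustError("query_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    lab = np.asarray(ds.labels)
    ref_rows, query_rows = [], []
    for t in sorted(set(ds.labels)):
        pool = np.nonzero(lab == t)[0]
        if pool.size < 2:
            raise KnowclustError(f"type {t!r} has fewer than 2 cells")
        n_query = int(round(query_fraction * pool.size))
        n_query = min(max(n_query, 1), pool.size - 1)
        picked = rng.permutation(pool)
        query_rows.append(picked[:n_query])
        ref_rows.append(picked[n_query:])
    ref_rows = np.sort(np.concatenate(ref_rows))
    query_rows = np.sort(np.concatenate(query_rows))

    def take(rows):
        return SimulatedDataset(
            ds.rna.subset_cells(rows),
            [ds.labels[i] for i in rows],
            ds.markers,
            adt=ds.adt.subset_cells(rows) if ds.adt is not None else None,
            coarse_labels=[ds.coarse_labels[i] for i in rows]
            if ds.coarse_labels is not None else None,
            protein_markers=ds.protein_markers,
        )

    return take(ref_rows), take(query_rows)
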
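"""Core in-memory containers shared across the package.

The in-memory convention everywhere is cells x features, regardless of the
on-disk orientation of the input files.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Sequence

import numpy as np

MODALITIES = ("RNA", "ADT", "ACTIVITY", "OTHER")
STATES = ("counts", "lognorm", "clr", "standardized")


class KnowclustError(ValueError):
    """Base class for user-facing validation errors."""


@dataclass
class ExpressionMatrix:
    """A cells x features expression matrix for one modality.

    Parameters
    ----------
    values
        Dense 2-D float array, one row per cell.
    cell_ids, feature_names
        Unique identifiers for rows and columns.
    modality
        One of ``RNA``, ``ADT``, ``ACTIVITY``, ``OTHER``.
    state
        Processing state tag: ``counts`` (raw, non-negative), ``lognorm``,
        ``clr`` or ``standardized``.
    """

    values: np.ndarray
    cell_ids: list[str]
    feature_names: list[str]
    modality: str = "RNA"
    state: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        if self.values.ndim != 2:
            raise KnowclustError("expression values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.cell_ids):
            raise KnowclustError(
                f"row count {n} does not match {len(self.cell_ids)} cell ids"
            )
        if p != len(self.feature_names):
            raise KnowclustError(
                f"column count {p} does not match {len(self.feature_names)} feature names"
            )
        for label, names in (("cell", self.cell_ids), ("feature", self.feature_names)):
            dupes = _duplicates(names)
            if dupes:
                raise KnowclustError(f"duplicate {label} names: {sorted(dupes)}")
        if self.modality not in MODALITIES:
            raise KnowclustError(f"unknown modality {self.modality!r}")
        if self.state not in STATES:
            raise KnowclustError(f"unknown state {self.state!r}")
        if self.state == "counts" and np.any(self.values < 0):
            raise KnowclustError("counts matrix contains negative values")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, state: str) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values, list(self.cell_ids), list(self.feature_names), self.modality, state
        )

    def subset_features(self, names: Sequence[str]) -> "ExpressionMatrix":
        index = {f: i for i, f in enumerate(self.feature_names)}
        cols = [index[n] for n in names]
        return ExpressionMatrix(
            self.values[:, cols], list(self.cell_ids), [str(n) for n in names],
            self.modality, self.state,
        )

    def subset_cells(self, rows: Sequence[int]) -> "ExpressionMatrix":
        rows = list(rows)
        return ExpressionMatrix(
            self.values[rows], [self.cell_ids[i] for i in rows],
            list(self.feature_names), self.modality, self.state,
        )


def _duplicates(names: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for n in names:
        if n in seen:
            dupes.add(n)
        seen.add(n)
    return dupes


def check_labels(labels: Sequence[str], expr: ExpressionMatrix) -> list[str]:
    """Validate a per-cell label vector against an expression matrix."""
    labels = [str(x) for x in labels]
    if len(labels) != expr.n_cells:
        raise KnowclustError(
            f"{len(labels)} labels for {expr.n_cells} cells"
        )
    if len(set(labels)) < 1:
        raise KnowclustError("label vector is empty")
    return labels


@dataclass
class RunConfig:
    """Tunable parameters of the clustering run.

    Defaults follow the framework's published settings: 5% highly variable
    genes, top 10% of each reference type's identity genes for matching,
    50 identity genes per type, a k-sweep up to 20 and a 30-cell floor per
    cluster.
    """

    hvg_fraction: float = 0.05
    top_gene_fraction: float = 0.10
    n_identity_genes: int = 50
    k_max: int = 20
    min_cells: int = 30
    min_match_genes: int = 3
    latent_dim: int = 16
    hidden_widths: tuple[int, ...] = (64,)
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 64
    activation: str = "tanh"
    n_neighbors: int = 12
    seed: int = 0
    unassigned_threshold: float | None = None
    fisher_variant: str = "weighted_mean"  # or "tanh_of_weighted_rho"
    # Split acceptance during recursion: "all_children" demands every child
    # cluster align with its matched reference identity better than
    # size-matched random subsets of the parent (a permutation null);
    # "aggregate" compares the children's pooled p_k against the parent.
    split_rule: str = "all_children"
    split_null_draws: int = 15
    split_z: float = 1.5
    # Add the knowledgebase union genes (those present in the query) to the
    # RNA feature space alongside the data-driven HVGs.  Rare cell types
    # contribute too little global variance for their markers to survive
    # variance ranking; the reference-derived identity genes keep them
    # visible to the embedding.
    include_kb_genes: bool = True

    def __post_init__(self) -> None:
        for name in ("hvg_fraction", "top_gene_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise KnowclustError(f"{name} must lie in (0, 1], got {v}")
        if self.k_max < 2:
            raise KnowclustError("k_max must be >= 2")
        if self.min_cells < 1:
            raise KnowclustError("min_cells must be >= 1")
        if self.n_identity_genes < 1:
            raise KnowclustError("n_identity_genes must be >= 1")
        if self.epochs < 1:
            raise KnowclustError("epochs must be >= 1")
        if int(self.seed) != self.seed:
            raise KnowclustError("seed must be an integer")
        self.hidden_widths = tuple(int(w) for w in self.hidden_widths)
        if self.fisher_variant not in ("weighted_mean", "tanh_of_weighted_rho"):
            raise KnowclustError(f"unknown fisher_variant {self.fisher_variant!r}")
        if self.split_rule not in ("all_children", "aggregate"):
            raise KnowclustError(f"unknown split_rule {self.split_rule!r}")

    @classmethod
    def field_names(cls) -> set[str]:
        return {f.name for f in fields(cls)}

    def replace(self, **kw) -> "RunConfig":
        return replace(self, **kw)
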
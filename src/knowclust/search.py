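"""Spectral k-sweep, score maximization and recursive cluster refinement.

The sweep clusters the affinity graph at every k in [2, k_max], scores each
partition (knowledge agreement x explained variance) and keeps the best valid
one.  Each initial cluster is then refined recursively: its cells are
re-embedded on the stacked representation [latent | input block], re-swept,
and a split is accepted only when no child falls below the minimum cluster
size and the split demonstrably improves knowledgebase alignment (see
``_accept_split``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans

from .containers import ExpressionMatrix, KnowclustError, RunConfig
from .embed import AutoencoderSpec, build_affinity, train_autoencoder
from .kb import Knowledgebase
from .preprocess import stack
from .scoring import (
    KnowledgebaseAligner, MatchResult, PartitionScore, match_cluster,
    partition_score, pseudo_bulk,
)


def spectral_embedding(A: np.ndarray, k_max: int) -> np.ndarray:
    """First k_max eigenvectors (ascending eigenvalue) of the symmetric
    normalized Laplacian L = I - D^{-1/2} A D^{-1/2}."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    deg = A.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(np.maximum(deg, np.finfo(float).tiny))
    L = -A * inv_sqrt[:, None] * inv_sqrt[None, :]
    L[np.diag_indices(n)] += 1.0
    L = 0.5 * (L + L.T)
    _, vecs = scipy.linalg.eigh(L, subset_by_index=[0, min(k_max, n) - 1])
    return vecs


def _embedding_rows(vecs: np.ndarray, k: int) -> np.ndarray:
    U = vecs[:, :k]
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    return U / np.where(norms > 0, norms, 1.0)


def _kmeans_on_rows(vecs: np.ndarray, k: int, seed: int) -> np.ndarray:
    km = KMeans(n_clusters=k, init="k-means++", n_init=10,
                random_state=int(seed) % (2**31))
    return km.fit_predict(_embedding_rows(vecs, k))


def spectral_cluster(A: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Normalized spectral clustering of an affinity matrix into k groups."""
    n = A.shape[0]
    if not (2 <= k <= n):
        raise KnowclustError(f"k={k} must lie in [2, {n}]")
    vecs = spectral_embedding(A, k)
    return _kmeans_on_rows(vecs, k, seed)


@dataclass
class SweepResult:
    """Per-k score table for one sweep plus the best valid partition."""

    table: list[PartitionScore]
    assignments: dict[int, np.ndarray]
    best_k: int | None
    best_assignment: np.ndarray | None

    @property
    def best(self) -> PartitionScore | None:
        if self.best_k is None:
            return None
        return next(s for s in self.table if s.k == self.best_k)


def sweep(
    Z: np.ndarray,
    expr_lognorm: ExpressionMatrix,
    kb: Knowledgebase,
    config: RunConfig,
    seed: int | None = None,
    affinity: np.ndarray | None = None,
) -> SweepResult:
    """Sweep k from 2 to min(k_max, n // min_cells) and keep the best score.

    The affinity graph and its spectral embedding are built once; ties on the
    best score break toward the smallest k (parsimony).
    """
    n = Z.shape[0]
    if n < 2 * config.min_cells:
        raise KnowclustError(
            f"{n} cells cannot be split with min_cells={config.min_cells}"
        )
    seed = config.seed if seed is None else seed
    k_hi = min(config.k_max, n // config.min_cells)
    if affinity is None:
        affinity = build_affinity(Z, min(config.n_neighbors, n - 1))
    vecs = spectral_embedding(affinity, k_hi)
    table: list[PartitionScore] = []
    assignments: dict[int, np.ndarray] = {}
    best_k, best_score = None, -np.inf
    for k in range(2, k_hi + 1):
        labels = _kmeans_on_rows(vecs, k, seed)
        # Explained variance is judged in the k-dim spectral embedding that
        # was clustered: there BSS/TSS peaks at the eigengap instead of
        # growing monotonically with k.
        ps = partition_score(_embedding_rows(vecs, k), expr_lognorm, labels, kb, config)
        ps.k = k  # k requested; empty spectral clusters keep the request index
        table.append(ps)
        assignments[k] = labels
        if ps.valid and ps.score > best_score:
            best_k, best_score = k, ps.score
    best_assignment = assignments[best_k] if best_k is not None else None
    return SweepResult(table, assignments, best_k, best_assignment)


@dataclass
class SplitNode:
    """One node of the recursive split tree."""

    path: str
    depth: int
    cell_index: np.ndarray
    match: MatchResult
    sweep_trace: list[dict] = field(default_factory=list)
    children: list["SplitNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["SplitNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def as_dict(self) -> dict:
        return {
            "path": self.path,
            "depth": self.depth,
            "n_cells": int(self.cell_index.size),
            "best_type": self.match.best_type,
            "rho": self.match.rho,
            "children": [c.as_dict() for c in self.children],
        }


def _node_seed(base: int, depth: int, ordinal: int) -> int:
    return (int(base) + 1009 * (depth + 1) + 9176 * (ordinal + 1)) % (2**31)


def _match_subset(
    expr_lognorm: ExpressionMatrix, idx: np.ndarray, kb: Knowledgebase,
    config: RunConfig, cluster_id: int = 0, full_union: bool = False,
) -> MatchResult:
    sub = expr_lognorm.subset_cells(idx)
    profile = pseudo_bulk(sub, np.zeros(idx.size, dtype=int))[0]
    profile.cluster_id = cluster_id
    frac = 1.0 if full_union else config.top_gene_fraction
    return match_cluster(profile, kb, frac, config.min_match_genes)


def _accept_split(
    best: PartitionScore,
    parent_match: MatchResult,
    child_matches: list[MatchResult],
    idx: np.ndarray,
    aligner: KnowledgebaseAligner,
    rng: np.random.Generator,
    config: RunConfig,
) -> bool:
    """A split must improve knowledgebase alignment over its parent.

    ``all_children`` (default): the split must isolate at least one genuine
    subpopulation — some child's alignment with its matched reference
    identity must exceed, by at least ``split_z`` null standard deviations,
    the alignment of size-matched random subsets of the parent with that same
    identity (a permutation null for "no substructure").  The null cancels
    the small-sample attenuation of the Spearman estimate: fragments of a
    homogeneous cluster behave exactly like random subsets (z near 0), while
    a peeled-off subpopulation concentrates cells the random subsets dilute.
    Alignments are judged on the full union gene set.  ``aggregate``: the
    children's pooled p_k must strictly exceed the parent's best-match
    correlation.
    """
    if config.split_rule != "all_children":
        return best.p_k > parent_match.rho
    for m in child_matches:
        if m.best_type == "unassigned" or m.weight == 0:
            continue
        null = np.array([
            aligner.rho(rng.choice(idx, size=m.size, replace=False), m.best_type)
            for _ in range(config.split_null_draws)
        ])
        sd = max(null.std(), 1e-6)
        if (m.rho - null.mean()) / sd >= config.split_z:
            return True
    return False


def recursive_refine(
    idx: np.ndarray,
    Z_global: np.ndarray,
    processed_fn,
    expr_lognorm: ExpressionMatrix,
    kb: Knowledgebase,
    config: RunConfig,
    depth: int = 1,
    path: str = "0",
    aligner: KnowledgebaseAligner | None = None,
    _counter: list[int] | None = None,
) -> SplitNode:
    """Refine one cluster recursively via stacking and local re-sweeps.

    ``processed_fn(idx)`` rebuilds the normalized/HVG/standardized input for
    the cluster's cells — feature selection is repeated within the cluster,
    so genes that vary only inside it (e.g. markers of a rare subtype
    swamped globally) re-enter the representation.  A split is accepted iff
    the best local partition is valid (all children >= min_cells) and every
    child aligns better with the knowledgebase than the parent did
    (see ``_accept_split``); otherwise the node stays a leaf.
    """
    if _counter is None:
        _counter = [0]
    if aligner is None:
        aligner = KnowledgebaseAligner(expr_lognorm, kb)
    idx = np.asarray(idx)
    match = _match_subset(expr_lognorm, idx, kb, config)
    node = SplitNode(path, depth, idx, match)
    if idx.size < 2 * config.min_cells:
        return node
    ordinal = _counter[0]
    _counter[0] += 1
    node_seed = _node_seed(config.seed, depth, ordinal)
    stacked = stack(Z_global[idx], processed_fn(idx))
    spec = AutoencoderSpec(
        input_width=stacked.shape[1],
        hidden_widths=config.hidden_widths,
        latent_dim=min(config.latent_dim, stacked.shape[1] - 1),
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        batch_size=config.batch_size,
        activation=config.activation,
        seed=node_seed,
    )
    _, Z_local = train_autoencoder(stacked, spec)
    sub_lognorm = expr_lognorm.subset_cells(idx)
    local = sweep(Z_local, sub_lognorm, kb, config, seed=node_seed)
    node.sweep_trace = [s.as_dict() for s in local.table]
    null_rng = np.random.default_rng((node_seed + 7919) % (2**31))
    # Only the best-scoring valid partition is a split candidate; testing
    # many k values per node would inflate the false-split rate of the
    # permutation test.
    candidates = [local.best] if local.best is not None else []
    accepted = None
    for cand in candidates:
        assignment = local.assignments[cand.k]
        child_indices = [
            idx[assignment == cid] for cid in np.unique(assignment)
        ]
        child_matches = [
            _match_subset(expr_lognorm, ci, kb, config, full_union=True)
            for ci in child_indices
        ]
        if _accept_split(cand, match, child_matches, idx, aligner, null_rng, config):
            accepted = (assignment, child_indices)
            break
    if accepted is None:
        return node
    assignment, child_indices = accepted
    for child_id, child_idx in zip(np.unique(assignment), child_indices):
        child = recursive_refine(
            child_idx, Z_global, processed_fn, expr_lognorm, kb, config,
            depth=depth + 1, path=f"{path}.{int(child_id)}", aligner=aligner,
            _counter=_counter,
        )
        node.children.append(child)
    return node
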
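"""Scoring a candidate partition against the knowledgebase.

Each cluster's pseudo-bulk profile is Spearman-correlated with every
reference type over the type's most informative genes; the best-match
correlations are Fisher-Z transformed, weighted by gene-set coverage and
averaged, and the inverse transform yields an overall knowledge-agreement
correlation p_k.  Multiplying by the explained-variance ratio BSS/TSS of the
partition gives the clustering score that the k-sweep maximizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .containers import ExpressionMatrix, KnowclustError, RunConfig
from .kb import Knowledgebase

RHO_CLAMP = 1.0 - 1e-7
UNASSIGNED = "unassigned"


@dataclass
class ClusterProfile:
    cluster_id: int
    size: int
    profile: np.ndarray  # mean lognorm expression, aligned to gene_names
    gene_names: list[str]


@dataclass
class MatchResult:
    """Best reference match for one cluster."""

    cluster_id: int
    best_type: str
    rho: float
    weight: float
    n_intersect: int
    z: float
    size: int = 0
    degenerate: bool = False


@dataclass
class PartitionScore:
    """Score of one candidate partition at cluster count k."""

    k: int
    matches: list[MatchResult]
    z_bar: float
    p_k: float
    bss_tss: float
    score: float
    valid: bool

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "p_k": self.p_k,
            "bss_tss": self.bss_tss,
            "score": self.score,
            "valid": self.valid,
            "matches": [
                {
                    "cluster": m.cluster_id, "best_type": m.best_type,
                    "rho": m.rho, "weight": m.weight,
                    "n_intersect": m.n_intersect, "size": m.size,
                }
                for m in self.matches
            ],
        }


def pseudo_bulk(expr: ExpressionMatrix, assignment: np.ndarray) -> list[ClusterProfile]:
    """Per-cluster mean expression over cells (pseudo-bulk profiles)."""
    assignment = np.asarray(assignment)
    if assignment.shape[0] != expr.n_cells:
        raise KnowclustError("assignment length does not match cell count")
    ids = np.unique(assignment)
    profiles = []
    for cid in ids:
        mask = assignment == cid
        if not mask.any():
            raise KnowclustError(f"cluster {cid} is empty")
        profiles.append(
            ClusterProfile(int(cid), int(mask.sum()), expr.values[mask].mean(axis=0),
                           list(expr.feature_names))
        )
    return profiles


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Spearman rank correlation via Pearson on average-fractional ranks.

    Returns (rho, degenerate); a constant vector has undefined rank
    correlation and yields (0.0, True).  Equals the classical
    1 - 6*sum(d^2)/(G(G^2-1)) form exactly in the absence of ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise KnowclustError("spearman needs two equal-length vectors of size >= 3")
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return 0.0, True
    rho = float(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy))
    return max(-1.0, min(1.0, rho)), False


def top_match_genes(kb: Knowledgebase, type_name: str, top_gene_fraction: float) -> list[str]:
    """The matching gene set S_j for a reference type.

    The top ``top_gene_fraction`` of the type's ranking of the knowledgebase
    union genes (most differentially stably expressed first); manual
    knowledgebases without stored rankings fall back to the given order of
    the type's own gene set.
    """
    if kb.union_rankings is not None and type_name in kb.union_rankings:
        ranked = kb.union_rankings[type_name]
    else:
        ranked = kb.identity_genes[type_name]
    n = max(1, math.ceil(top_gene_fraction * len(ranked)))
    return ranked[:n]


def match_cluster(
    profile: ClusterProfile,
    kb: Knowledgebase,
    top_gene_fraction: float = 0.10,
    min_match_genes: int = 3,
) -> MatchResult:
    """Best-matching reference type for one cluster profile.

    For each type j, Spearman rho is computed over the intersection of the
    query genes with j's top matching genes; weight = |intersection| / |set|.
    The winner is the highest rho among types with enough intersecting genes;
    ties break by larger weight, then ascending type name.  If no type has
    enough genes the cluster is unassigned with zero weight.
    """
    gene_index = {g: i for i, g in enumerate(profile.gene_names)}
    best: tuple | None = None
    for t in kb.types:
        genes = top_match_genes(kb, t, top_gene_fraction)
        common = [g for g in genes if g in gene_index]
        if len(common) < max(3, min_match_genes):
            continue
        x = profile.profile[[gene_index[g] for g in common]]
        y = kb.profiles.loc[t, common].to_numpy(dtype=float)
        rho, degen = spearman(x, y)
        weight = len(common) / len(genes)
        key = (rho, weight, _NameDesc(t))
        if best is None or key > best[0]:
            best = (key, t, rho, weight, len(common), degen)
    if best is None:
        return MatchResult(profile.cluster_id, UNASSIGNED, 0.0, 0.0, 0, 0.0,
                           size=profile.size)
    _, t, rho, weight, n_int, degen = best
    z = fisher_z(rho, weight)
    return MatchResult(profile.cluster_id, t, rho, weight, n_int, z,
                       size=profile.size, degenerate=degen)


class _NameDesc(str):
    """Inverts string comparison so max() prefers the ascending name on ties."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)

    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


class KnowledgebaseAligner:
    """Fast full-signature alignment of cell subsets against reference types.

    Pre-extracts the query's union-gene submatrix and the rank-transformed
    reference profiles so that the Spearman correlation of any cell subset's
    pseudo-bulk with any type costs one mean and one ranking.
    """

    def __init__(self, expr_lognorm: ExpressionMatrix, kb: Knowledgebase) -> None:
        present = set(expr_lognorm.feature_names)
        self.genes = [g for g in kb.union_genes if g in present]
        index = {g: i for i, g in enumerate(expr_lognorm.feature_names)}
        cols = [index[g] for g in self.genes]
        self.V = expr_lognorm.values[:, cols]
        self._y = {
            t: kb.profiles.loc[t, self.genes].to_numpy(dtype=float) for t in kb.types
        }

    def rho(self, rows: np.ndarray, type_name: str) -> float:
        """Spearman rho of the subset's pseudo-bulk vs one reference profile,
        over the full union gene set present in the query."""
        if len(self.genes) < 3:
            return 0.0
        x = self.V[rows].mean(axis=0)
        return spearman(x, self._y[type_name])[0]


def clamp_rho(rho: float) -> float:
    return max(-RHO_CLAMP, min(RHO_CLAMP, float(rho)))


def fisher_z(rho: float, weight: float = 1.0) -> float:
    """Weighted Fisher Z: z = w * atanh(rho), with rho clamped off +/-1."""
    return float(weight) * math.atanh(clamp_rho(rho))


def inv_fisher(z: float) -> float:
    """Inverse Fisher transform back to the correlation scale."""
    return math.tanh(z)


def aggregate(matches: list[MatchResult], variant: str = "weighted_mean") -> tuple[float, float]:
    """Aggregate per-cluster correlations into (z_bar, p_k).

    ``weighted_mean`` (default): z_bar = sum(w*atanh(rho)) / sum(w), the
    weighted-Fisher meta-analytic mean; ``tanh_of_weighted_rho``: the
    alternative z = atanh(w*rho) averaged unweighted.  Unassigned clusters
    carry zero weight; with no weight at all, p_k = 0.
    """
    if not matches:
        raise KnowclustError("no matches to aggregate")
    if variant == "weighted_mean":
        wsum = sum(m.weight for m in matches)
        if wsum == 0:
            return 0.0, 0.0
        z_bar = sum(m.weight * math.atanh(clamp_rho(m.rho)) for m in matches) / wsum
    elif variant == "tanh_of_weighted_rho":
        z_bar = float(np.mean([math.atanh(clamp_rho(m.weight * m.rho)) for m in matches]))
    else:
        raise KnowclustError(f"unknown aggregation variant {variant!r}")
    return z_bar, inv_fisher(z_bar)


def bss_tss(Z: np.ndarray, assignment: np.ndarray) -> float:
    """Explained-variance ratio: between-cluster over total sum of squares."""
    Z = np.asarray(Z, dtype=float)
    assignment = np.asarray(assignment)
    if Z.shape[0] < 2:
        raise KnowclustError("need at least 2 cells")
    center = Z.mean(axis=0)
    tss = float(((Z - center) ** 2).sum())
    if tss == 0:
        return 0.0
    bss = 0.0
    for cid in np.unique(assignment):
        sub = Z[assignment == cid]
        bss += sub.shape[0] * float(((sub.mean(axis=0) - center) ** 2).sum())
    return min(1.0, bss / tss)


def partition_score(
    Z: np.ndarray,
    expr_lognorm: ExpressionMatrix,
    assignment: np.ndarray,
    kb: Knowledgebase,
    config: RunConfig,
) -> PartitionScore:
    """Score one partition: knowledge agreement p_k times explained variance.

    The partition is flagged invalid when any cluster is smaller than
    ``config.min_cells``.
    """
    assignment = np.asarray(assignment)
    profiles = pseudo_bulk(expr_lognorm, assignment)
    matches = [
        match_cluster(p, kb, config.top_gene_fraction, config.min_match_genes)
        for p in profiles
    ]
    z_bar, p_k = aggregate(matches, config.fisher_variant)
    ratio = bss_tss(Z, assignment)
    sizes = [p.size for p in profiles]
    valid = all(s >= config.min_cells for s in sizes)
    k = len(profiles)
    return PartitionScore(k, matches, z_bar, p_k, ratio, ratio * p_k, valid)
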
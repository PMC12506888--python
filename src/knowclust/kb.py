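"""Cell-type knowledgebase: identity genes and pseudo-bulk reference profiles.

Identity genes are selected per reference cell type either by a differential
stability statistic (genes stably and uniquely expressed in the type: high
fraction of non-zero cells, low coefficient of variation, contrasted against
the other types) or by one-vs-rest differential expression.  The knowledgebase
stores, per type, the ranked identity-gene list and the mean log-normalized
expression profile over the union of all identity genes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .containers import ExpressionMatrix, KnowclustError, check_labels
from .preprocess import log_normalize

KB_FORMAT_VERSION = 1


@dataclass
class StabilityScores:
    """Per-gene, per-type differential stability statistics.

    ``scores`` is features x types; higher means more stably and uniquely
    expressed in that type.  For every gene the scores sum to zero across
    types by construction (pairwise-difference antisymmetry).
    """

    scores: np.ndarray
    gene_names: list[str]
    type_names: list[str]


@dataclass
class Knowledgebase:
    """Reference cell types with ranked identity genes and pseudo-bulk profiles."""

    types: list[str]
    identity_genes: dict[str, list[str]]
    union_genes: list[str]
    profiles: pd.DataFrame  # types x union_genes
    method: str = "stability"
    # per type, the full union gene list ranked by that type's statistic
    # (descending stability or ascending DE p); used to pick the matching
    # gene sets.  Falls back to identity_genes when absent (manual kbs).
    union_rankings: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        if self.union_rankings is not None:
            union = set(self.union_genes)
            for t, ranked in self.union_rankings.items():
                if set(ranked) != union:
                    raise KnowclustError(
                        f"union ranking of {t!r} does not cover the union genes"
                    )
        if not self.types:
            raise KnowclustError("knowledgebase has no types")
        union = set(self.union_genes)
        for t in self.types:
            genes = self.identity_genes[t]
            if len(set(genes)) != len(genes):
                raise KnowclustError(f"duplicate identity genes for type {t!r}")
            missing = [g for g in genes if g not in union]
            if missing:
                raise KnowclustError(
                    f"identity genes of {t!r} missing from union: {missing[:5]}"
                )
        if list(self.profiles.index) != list(self.types):
            raise KnowclustError("profile rows must match type order")
        if list(self.profiles.columns) != list(self.union_genes):
            raise KnowclustError("profile columns must match union genes")

    @property
    def n_types(self) -> int:
        return len(self.types)


def stability_scores(expr: ExpressionMatrix, labels: Sequence[str]) -> StabilityScores:
    """Differential stability statistic per gene and reference type.

    Within each type t: z = fraction of cells expressing the gene, and
    cv = sd/mean (``+inf`` for an all-zero gene, i.e. worst stability).
    z and -cv are converted to within-type fractional ranks over genes,
    scaled to (0, 1], and averaged into a per-type summary s.  The score of
    gene g for type t is the mean difference of s against all other types:
    ``score = (1/(T-1)) * sum_{t' != t} (s_t - s_t')``.
    """
    if expr.state != "lognorm":
        raise KnowclustError("stability_scores expects log-normalized expression")
    labels = check_labels(labels, expr)
    types = sorted(set(labels))
    if len(types) < 2:
        raise KnowclustError("need at least 2 reference types")
    lab = np.asarray(labels)
    X = expr.values
    n_genes = X.shape[1]
    s = np.empty((n_genes, len(types)))
    for j, t in enumerate(types):
        sub = X[lab == t]
        if sub.shape[0] < 2:
            raise KnowclustError(f"type {t!r} has fewer than 2 cells")
        nz = (sub > 0).mean(axis=0)
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean > 0, sd / mean, np.inf)
        rank_nz = rankdata(nz, method="average") / n_genes
        rank_stab = rankdata(-cv, method="average") / n_genes
        s[:, j] = 0.5 * (rank_nz + rank_stab)
    T = len(types)
    scores = (T / (T - 1)) * (s - s.mean(axis=1, keepdims=True))
    return StabilityScores(scores, list(expr.feature_names), types)


def select_identity_genes(scores: StabilityScores, n_top: int) -> dict[str, list[str]]:
    """Top ``n_top`` genes per type by descending score; ties by ascending name."""
    if n_top < 1:
        raise KnowclustError("n_top must be >= 1")
    if n_top > len(scores.gene_names):
        raise KnowclustError(
            f"n_top={n_top} exceeds the {len(scores.gene_names)} scored genes"
        )
    out: dict[str, list[str]] = {}
    names = np.asarray(scores.gene_names)
    for j, t in enumerate(scores.type_names):
        order = sorted(range(len(names)), key=lambda i: (-scores.scores[i, j], names[i]))
        out[t] = [str(names[i]) for i in order[:n_top]]
    return out


def de_markers(
    expr: ExpressionMatrix,
    labels: Sequence[str],
    alpha: float = 0.05,
    return_pvalues: bool = False,
):
    """One-vs-rest Wilcoxon rank-sum markers per type.

    A gene is kept for a type when its Bonferroni-corrected two-sided p-value
    (factor = n_genes x n_types) is below ``alpha`` and its mean expression is
    higher inside the type than outside.  Genes are ranked by ascending p.
    """
    if expr.state != "lognorm":
        raise KnowclustError("de_markers expects log-normalized expression")
    labels = check_labels(labels, expr)
    lab = np.asarray(labels)
    types = sorted(set(labels))
    X = expr.values
    names = np.asarray(expr.feature_names)
    n_tests = X.shape[1] * len(types)
    markers: dict[str, list[str]] = {}
    pvals: dict[str, np.ndarray] = {}
    for t in types:
        mask = lab == t
        if mask.sum() < 3:
            raise KnowclustError(f"type {t!r} has fewer than 3 cells")
        inside, outside = X[mask], X[~mask]
        with np.errstate(all="ignore"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = mannwhitneyu(
                    inside, outside, axis=0, alternative="two-sided",
                    method="asymptotic",
                )
        p = np.minimum(res.pvalue * n_tests, 1.0)
        up = inside.mean(axis=0) > outside.mean(axis=0)
        keep = (p < alpha) & up
        order = np.lexsort((names, p))
        ranked = [str(names[i]) for i in order if keep[i]]
        markers[t] = ranked
        pvals[t] = p
    if return_pvalues:
        return markers, pvals
    return markers


def build_knowledgebase(
    expr: ExpressionMatrix,
    labels: Sequence[str],
    method: str = "stability",
    n_top: int = 50,
    alpha: float = 0.05,
) -> Knowledgebase:
    """Build the knowledgebase from a labeled reference count matrix.

    Counts are log-normalized, identity genes derived by ``method``
    (``stability`` or ``de``), and per-type profiles are the mean
    log-normalized expression over the union of all identity genes.
    """
    labels = check_labels(labels, expr)
    logn = log_normalize(expr) if expr.state == "counts" else expr
    names = np.asarray(logn.feature_names)
    if method == "stability":
        scores = stability_scores(logn, labels)
        identity = select_identity_genes(scores, n_top)
        gene_pos = {g: i for i, g in enumerate(scores.gene_names)}
        type_pos = {t: j for j, t in enumerate(scores.type_names)}
        sort_key = lambda t: (lambda g: (-scores.scores[gene_pos[g], type_pos[t]], g))
    elif method == "de":
        markers, pvals = de_markers(logn, labels, alpha=alpha, return_pvalues=True)
        gene_pos = {g: i for i, g in enumerate(logn.feature_names)}
        identity = {}
        for t, genes in markers.items():
            if not genes:
                warnings.warn(
                    f"no significant markers for type {t!r}; "
                    f"keeping its {n_top} smallest-p genes"
                )
                order = np.lexsort((names, pvals[t]))
                genes = [str(names[i]) for i in order[:n_top]]
            identity[t] = genes[:n_top]
        sort_key = lambda t: (lambda g: (pvals[t][gene_pos[g]], g))
    else:
        raise KnowclustError(f"unknown knowledgebase method {method!r}")
    union = sorted(set(g for genes in identity.values() for g in genes))
    rankings = {t: sorted(union, key=sort_key(t)) for t in identity}
    return _assemble(logn, labels, identity, method, rankings)


def _assemble(
    logn: ExpressionMatrix, labels: Sequence[str],
    identity: Mapping[str, list[str]], method: str,
    rankings: dict[str, list[str]] | None = None,
) -> Knowledgebase:
    types = sorted(identity)
    union = sorted(set(g for genes in identity.values() for g in genes))
    lab = np.asarray(list(labels))
    sub = logn.subset_features(union)
    rows = [sub.values[lab == t].mean(axis=0) for t in types]
    profiles = pd.DataFrame(np.vstack(rows), index=types, columns=union)
    return Knowledgebase(types, {t: list(identity[t]) for t in types}, union,
                         profiles, method, rankings)


def kb_from_gene_sets(
    gene_sets: Mapping[str, Sequence[str]],
    profiles: Mapping[str, Mapping[str, float]],
) -> Knowledgebase:
    """Build a manual knowledgebase from named gene sets and averaged profiles.

    Ranking within a set is its given order.  Every gene of a set must have a
    profile value for that set's type.
    """
    types = sorted(gene_sets)
    for t in types:
        if t not in profiles:
            raise KnowclustError(f"no profile for gene set {t!r}")
        missing = [g for g in gene_sets[t] if g not in profiles[t]]
        if missing:
            raise KnowclustError(
                f"profile of set {t!r} is missing genes: {missing[:5]}"
            )
    identity = {t: [str(g) for g in gene_sets[t]] for t in types}
    union = sorted(set(g for genes in identity.values() for g in genes))
    mat = np.zeros((len(types), len(union)))
    for i, t in enumerate(types):
        for j, g in enumerate(union):
            mat[i, j] = profiles[t].get(g, 0.0)
    pf = pd.DataFrame(mat, index=types, columns=union)
    return Knowledgebase(types, identity, union, pf, "manual")


def save_kb(kb: Knowledgebase, path: str | Path) -> None:
    """Write kb metadata + identity genes as JSON and profiles as TSV."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": KB_FORMAT_VERSION,
        "method": kb.method,
        "types": kb.types,
        "identity_genes": kb.identity_genes,
        "union_genes": kb.union_genes,
        "union_rankings": kb.union_rankings,
    }
    with open(path / "kb.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    kb.profiles.to_csv(path / "kb_profiles.tsv", sep="\t", index_label="type")


def load_kb(path: str | Path) -> Knowledgebase:
    path = Path(path)
    with open(path / "kb.json") as fh:
        meta = json.load(fh)
    if meta.get("format_version") != KB_FORMAT_VERSION:
        raise KnowclustError(
            f"knowledgebase format version {meta.get('format_version')} "
            f"!= supported {KB_FORMAT_VERSION}"
        )
    profiles = pd.read_csv(path / "kb_profiles.tsv", sep="\t", index_col="type")
    profiles.index = profiles.index.astype(str)
    try:
        aligned = profiles.loc[meta["types"], meta["union_genes"]]
    except KeyError as exc:
        raise KnowclustError(
            f"kb profiles at {path} do not cover the recorded types/genes: {exc}"
        ) from exc
    rankings = meta.get("union_rankings")
    if rankings is not None:
        rankings = {str(t): [str(g) for g in gs] for t, gs in rankings.items()}
    return Knowledgebase(
        [str(t) for t in meta["types"]],
        {str(t): [str(g) for g in gs] for t, gs in meta["identity_genes"].items()},
        [str(g) for g in meta["union_genes"]],
        aligned,
        meta["method"],
        rankings,
    )
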
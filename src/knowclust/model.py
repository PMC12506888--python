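"""Model/Results interface to knowledge-guided clustering.

``KnowledgeGuidedClustering`` holds the query modalities, the knowledgebase
and the run configuration; ``fit()`` executes the full pipeline (per-modality
normalization, feature selection, autoencoder embedding, spectral k-sweep,
recursive refinement) and returns a ``ClusteringResults`` with the final
labels, per-cluster reference annotations, the split tree and the score
traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, KnowclustError, RunConfig
from .embed import AutoencoderSpec, build_affinity, train_autoencoder
from .kb import Knowledgebase
from .preprocess import (
    clr_normalize, concat_modalities, log_normalize, select_hvg, standardize,
)
from .scoring import UNASSIGNED, KnowledgebaseAligner, MatchResult
from .search import SplitNode, recursive_refine, sweep


@dataclass
class ResultTable:
    """Per-cell output table plus run-level metadata; written by io.write_result."""

    table: pd.DataFrame  # cell_id, cluster, matched_type, correlation
    n_clusters: int
    score_trace: dict


class KnowledgeGuidedClustering:
    """Knowledge-guided clustering of one or more query modalities.

    Parameters
    ----------
    rna
        RNA counts matrix (cells x genes); required, and the only modality
        compared against the knowledgebase.
    kb
        Reference knowledgebase (identity genes + pseudo-bulk profiles).
    adt, activity
        Optional additional modalities over the same cells: antibody-derived
        tag counts (CLR-normalized) and gene-activity scores (log-normalized).
    config
        Run configuration; defaults follow the published settings.
    """

    def __init__(
        self,
        rna: ExpressionMatrix,
        kb: Knowledgebase,
        adt: ExpressionMatrix | None = None,
        activity: ExpressionMatrix | None = None,
        config: RunConfig | None = None,
    ) -> None:
        self.config = config or RunConfig()
        if rna.state != "counts":
            raise KnowclustError("query RNA must be raw counts")
        self.rna = rna
        self.adt = adt
        self.activity = activity
        self.kb = kb
        for other in (adt, activity):
            if other is not None and other.cell_ids != rna.cell_ids:
                raise KnowclustError("modalities do not share an identical cell order")
        n_shared = len(set(rna.feature_names) & set(kb.union_genes))
        if n_shared < 3:
            raise KnowclustError(
                "knowledgebase incompatible with query: fewer than 3 shared genes"
            )
        if rna.n_cells < 2 * self.config.min_cells:
            raise KnowclustError(
                f"{rna.n_cells} cells cannot be clustered with "
                f"min_cells={self.config.min_cells}"
            )

    @classmethod
    def from_files(cls, rna_path, kb_path, adt_path=None, activity_path=None,
                   config=None, **read_kw):
        from . import io
        from .kb import load_kb
        rna = io.read_expression_dense(rna_path, modality="RNA", **read_kw)
        adt = io.read_expression_dense(adt_path, modality="ADT") if adt_path else None
        act = (io.read_expression_dense(activity_path, modality="ACTIVITY")
               if activity_path else None)
        return cls(rna, load_kb(kb_path), adt=adt, activity=act, config=config)

    # -- pipeline pieces -------------------------------------------------
    def _processed_input(self, idx: np.ndarray | None = None) -> np.ndarray:
        """Normalize/HVG/standardize every modality for a cell subset.

        Called with ``idx=None`` for the full query; during recursion it is
        re-run per cluster, so feature selection adapts to each node.
        """
        cfg = self.config

        def sub(expr):
            return expr if idx is None else expr.subset_cells(idx)

        from .preprocess import MIN_HVG

        rna_norm = log_normalize(sub(self.rna))
        hvg = select_hvg(rna_norm, cfg.hvg_fraction, min_features=MIN_HVG)
        if cfg.include_kb_genes:
            keep = set(hvg.feature_names) | (
                set(self.kb.union_genes) & set(rna_norm.feature_names)
            )
            hvg = rna_norm.subset_features(
                [g for g in rna_norm.feature_names if g in keep]
            )
        blocks = [standardize(hvg)]
        if self.activity is not None:
            blocks.append(
                standardize(select_hvg(log_normalize(sub(self.activity)),
                                       cfg.hvg_fraction, min_features=MIN_HVG))
            )
        if self.adt is not None:
            blocks.append(standardize(clr_normalize(sub(self.adt))))
        return concat_modalities(blocks)

    def fit(self) -> "ClusteringResults":
        """Run the pipeline and return the fitted results."""
        cfg = self.config
        self._rna_lognorm = log_normalize(self.rna)
        X = self._processed_input()
        spec = AutoencoderSpec(
            input_width=X.shape[1],
            hidden_widths=cfg.hidden_widths,
            latent_dim=min(cfg.latent_dim, X.shape[1] - 1),
            learning_rate=cfg.learning_rate,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            activation=cfg.activation,
            seed=cfg.seed,
        )
        model, Z = train_autoencoder(X, spec)
        affinity = build_affinity(Z, min(cfg.n_neighbors, X.shape[0] - 1))
        expr_lognorm = self._rna_lognorm
        aligner = KnowledgebaseAligner(expr_lognorm, self.kb)
        top = sweep(Z, expr_lognorm, self.kb, cfg, affinity=affinity)
        all_idx = np.arange(X.shape[0])
        from .search import _match_subset
        root = SplitNode("root", 0, all_idx, _match_subset(expr_lognorm, all_idx, self.kb, cfg))
        root.sweep_trace = [s.as_dict() for s in top.table]
        counter = [0]
        if top.best_k is None:
            pass  # no valid initial split: the whole dataset is one cluster
        else:
            for cid in np.unique(top.best_assignment):
                idx = all_idx[top.best_assignment == cid]
                child = recursive_refine(
                    idx, Z, self._processed_input, expr_lognorm, self.kb, cfg,
                    depth=1, path=str(int(cid)), aligner=aligner, _counter=counter,
                )
                root.children.append(child)
        leaves = root.leaves()
        labels = np.empty(X.shape[0], dtype=int)
        annotations: list[MatchResult] = []
        for new_id, leaf in enumerate(leaves):  # traversal order: dense, stable
            labels[leaf.cell_index] = new_id
            m = leaf.match
            m.cluster_id = new_id
            annotations.append(m)
        return ClusteringResults(self, labels, annotations, root, Z, model.loss_trace)


class ClusteringResults:
    """Fitted results: final labels, annotations, split tree and diagnostics."""

    def __init__(self, model, labels, annotations, tree, latent, loss_trace):
        self.model = model
        self.config: RunConfig = model.config
        self.labels = np.asarray(labels)
        self.annotations: list[MatchResult] = annotations
        self.tree: SplitNode = tree
        self.latent = latent
        self.loss_trace = loss_trace

    @property
    def n_clusters(self) -> int:
        return len(self.annotations)

    @property
    def score_trace(self) -> dict:
        trace = {"root": self.tree.sweep_trace}

        def walk(node):
            for c in node.children:
                if c.sweep_trace:
                    trace[c.path] = c.sweep_trace
                walk(c)

        walk(self.tree)
        return trace

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)

    def annotate(self, threshold: float | None = None) -> ResultTable:
        """Per-cell result table with cluster-level reference annotations.

        With a correlation ``threshold``, clusters whose best-match rho falls
        below it are reported as unassigned (the rho is still printed).
        """
        if threshold is None:
            threshold = self.config.unassigned_threshold
        matched, rho = {}, {}
        for m in self.annotations:
            name = m.best_type
            if threshold is not None and m.rho < threshold:
                name = UNASSIGNED
            matched[m.cluster_id] = name
            rho[m.cluster_id] = m.rho
        df = pd.DataFrame(
            {
                "cell_id": self.model.rna.cell_ids,
                "cluster": self.labels,
                "matched_type": [matched[c] for c in self.labels],
                "correlation": [rho[c] for c in self.labels],
            }
        )
        return ResultTable(df, self.n_clusters, self.score_trace)

    def summary(self) -> str:
        """Human-readable per-cluster summary."""
        sizes = self.cluster_sizes()
        lines = [
            "Knowledge-guided clustering results",
            "===================================",
            f"cells:           {self.labels.size}",
            f"final clusters:  {self.n_clusters}",
            f"reference types: {self.model.kb.n_types} ({self.model.kb.method})",
            "",
            f"{'cluster':>7} {'size':>6} {'rho':>8} {'genes':>6}  matched type",
        ]
        for m in sorted(self.annotations, key=lambda m: m.cluster_id):
            lines.append(
                f"{m.cluster_id:>7} {sizes[m.cluster_id]:>6} {m.rho:>8.4f} "
                f"{m.n_intersect:>6}  {m.best_type}"
            )
        return "\n".join(lines)


def cluster_query(
    rna: ExpressionMatrix,
    kb: Knowledgebase,
    config: RunConfig | None = None,
    adt: ExpressionMatrix | None = None,
    activity: ExpressionMatrix | None = None,
) -> ClusteringResults:
    """Functional wrapper: build the model and fit it."""
    return KnowledgeGuidedClustering(
        rna, kb, adt=adt, activity=activity, config=config
    ).fit()
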
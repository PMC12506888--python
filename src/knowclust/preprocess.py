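"""Per-modality normalization, feature selection and standardization."""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .containers import ExpressionMatrix, KnowclustError

# HVG selection never drops below this many features so that small
# simulated inputs keep a workable feature space.
MIN_HVG = 50


def log_normalize(expr: ExpressionMatrix, scale_factor: float = 10_000.0) -> ExpressionMatrix:
    """Library-size normalize and log-transform: ln(1 + x * sf / libsize)."""
    if expr.state != "counts":
        raise KnowclustError("log_normalize expects raw counts")
    lib = expr.values.sum(axis=1)
    zero = lib <= 0
    if np.any(zero):
        bad = [expr.cell_ids[i] for i in np.nonzero(zero)[0]]
        raise KnowclustError(f"cells with zero library size: {bad[:10]}")
    out = np.log1p(expr.values * (scale_factor / lib[:, None]))
    return expr.with_values(out, "lognorm")


def clr_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Centered log-ratio across cells, per feature (ADT convention)."""
    if expr.state != "counts":
        raise KnowclustError("clr_normalize expects raw counts")
    logged = np.log1p(expr.values)
    out = logged - logged.mean(axis=0, keepdims=True)
    return expr.with_values(out, "clr")


def select_hvg(
    expr: ExpressionMatrix, fraction: float = 0.05, min_features: int = 1
) -> ExpressionMatrix:
    """Keep the ceil(fraction * p) highest-variance features.

    Ties are broken by ascending feature name; the original column order is
    preserved among the kept set.  ``min_features`` floors the kept count
    (the pipeline uses MIN_HVG so tiny inputs keep a workable feature space).
    """
    if not (0 < fraction <= 1):
        raise KnowclustError(f"fraction must lie in (0, 1], got {fraction}")
    if expr.state not in ("lognorm", "clr"):
        raise KnowclustError("select_hvg expects normalized expression")
    var = expr.values.var(axis=0)
    if np.all(var == 0):
        raise KnowclustError("all features are constant; nothing to select")
    p = expr.n_features
    n_keep = min(p, max(math.ceil(fraction * p), min(min_features, p)))
    names = np.asarray(expr.feature_names)
    order = sorted(range(p), key=lambda i: (-var[i], names[i]))
    kept = sorted(order[:n_keep])  # original column order
    return expr.subset_features([expr.feature_names[i] for i in kept])


def standardize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Zero-mean, unit-variance per feature; constant features map to zero."""
    out = standardize_matrix(expr.values)
    return expr.with_values(out, "standardized")


def standardize_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd


def concat_modalities(processed: Sequence[ExpressionMatrix]) -> np.ndarray:
    """Column-wise concatenation of standardized modalities sharing cell order."""
    if not processed:
        raise KnowclustError("no modalities to concatenate")
    first = processed[0]
    for m in processed[1:]:
        if m.cell_ids != first.cell_ids:
            raise KnowclustError("modalities do not share an identical cell order")
    return np.hstack([m.values for m in processed])


def stack(Z: np.ndarray, X_sub: np.ndarray) -> np.ndarray:
    """Stacking: [standardize(Z) | standardize(X_sub)] for a cluster's cells.

    Concatenating the learned latent coordinates with the cluster's own input
    block lets the next round of embedding refine features within the cluster
    while retaining the global geometry.
    """
    Z = np.asarray(Z, dtype=float)
    X_sub = np.asarray(X_sub, dtype=float)
    if X_sub.size == 0:
        return standardize_matrix(Z)
    if Z.shape[0] != X_sub.shape[0]:
        raise KnowclustError(
            f"latent block has {Z.shape[0]} rows, input block {X_sub.shape[0]}"
        )
    return np.hstack([standardize_matrix(Z), standardize_matrix(X_sub)])
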
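"""Evaluation metrics (ARI, ADR, min-max scaling) and benchmark subsampling."""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, KnowclustError, check_labels


def contingency(truth: Sequence, pred: Sequence) -> np.ndarray:
    a = pd.Categorical(list(map(str, truth)))
    b = pd.Categorical(list(map(str, pred)))
    table = np.zeros((len(a.categories), len(b.categories)), dtype=np.int64)
    np.add.at(table, (a.codes, b.codes), 1)
    return table


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return x * (x - 1) / 2.0


def ari(truth: Sequence, pred: Sequence) -> float:
    """Adjusted Rand index via the pair-counting contingency-table formula.

    Degenerate denominator (both labelings trivial): 1 when the two
    partitions are identical, else 0.
    """
    truth, pred = list(truth), list(pred)
    if len(truth) != len(pred) or len(truth) < 2:
        raise KnowclustError("ari needs two equal-length labelings of size >= 2")
    table = contingency(truth, pred)
    n = table.sum()
    sum_ij = _comb2(table).sum()
    sum_a = _comb2(table.sum(axis=1)).sum()
    sum_b = _comb2(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / _comb2(np.array(n))
    maxterm = 0.5 * (sum_a + sum_b)
    denom = maxterm - expected
    if denom == 0:
        same = _same_partition(truth, pred)
        return 1.0 if same else 0.0
    return float((sum_ij - expected) / denom)


def _same_partition(truth, pred) -> bool:
    groups_t = {}
    groups_p = {}
    for i, (t, p) in enumerate(zip(truth, pred)):
        groups_t.setdefault(t, set()).add(i)
        groups_p.setdefault(p, set()).add(i)
    return set(frozenset(g) for g in groups_t.values()) == set(
        frozenset(g) for g in groups_p.values()
    )


def adr(c_true: int, c_pred: int) -> float:
    """Absolute deviation ratio |c - c_hat| / c of predicted cluster counts."""
    if c_true < 1:
        raise KnowclustError("true cluster count must be >= 1")
    return abs(c_true - c_pred) / c_true


def minmax_scale(values: Sequence[float]) -> np.ndarray:
    """(v - min) / (max - min); a constant vector maps to all 0.5."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise KnowclustError("minmax_scale needs at least 2 values")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.full_like(v, 0.5)
    return (v - lo) / (hi - lo)


def scaled_adr(values: Sequence[float]) -> np.ndarray:
    """1 - minmax(ADR): higher is better, bounded in [0, 1]."""
    return 1.0 - minmax_scale(values)


def _subset(expr: ExpressionMatrix, labels: list[str], rows: np.ndarray):
    rows = np.sort(np.asarray(rows))
    return expr.subset_cells(rows), [labels[i] for i in rows]


def balanced_subsample(
    expr: ExpressionMatrix, labels: Sequence[str],
    n_types: int, cells_per_type: int, seed: int = 0,
):
    """Sample ``n_types`` types and ``cells_per_type`` cells per type, without
    replacement, deterministically per seed."""
    labels = check_labels(labels, expr)
    rng = np.random.default_rng(seed)
    lab = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    eligible = sorted(counts.index[counts >= cells_per_type])
    if len(eligible) < n_types:
        raise KnowclustError(
            f"only {len(eligible)} types have >= {cells_per_type} cells; "
            f"{n_types} requested"
        )
    chosen = rng.choice(eligible, size=n_types, replace=False)
    rows = []
    for t in chosen:
        pool = np.nonzero(lab == t)[0]
        rows.append(rng.choice(pool, size=cells_per_type, replace=False))
    return _subset(expr, labels, np.concatenate(rows))


def imbalanced_subsample(
    expr: ExpressionMatrix, labels: Sequence[str],
    n_major_cells: int = 200, ratio: int = 2, seed: int = 0,
    n_types: int = 10,
):
    """Ten types split evenly into major/minor groups at the given ratio.

    Major types keep ``n_major_cells`` cells, minor types
    ``n_major_cells // ratio``.
    """
    if ratio not in (2, 4, 8):
        warnings.warn(f"imbalance ratio {ratio} is a non-standard setting")
    labels = check_labels(labels, expr)
    rng = np.random.default_rng(seed)
    lab = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    eligible = sorted(counts.index[counts >= n_major_cells])
    if len(eligible) < n_types:
        raise KnowclustError(
            f"need {n_types} types with >= {n_major_cells} cells, have {len(eligible)}"
        )
    chosen = rng.choice(eligible, size=n_types, replace=False)
    major = set(rng.choice(chosen, size=n_types // 2, replace=False))
    rows = []
    for t in chosen:
        take = n_major_cells if t in major else max(1, n_major_cells // ratio)
        pool = np.nonzero(lab == t)[0]
        rows.append(rng.choice(pool, size=take, replace=False))
    return _subset(expr, labels, np.concatenate(rows))


def fraction_subsample(
    expr: ExpressionMatrix, labels: Sequence[str], fraction: float, seed: int = 0
):
    """Retain floor(fraction * n) cells sampled without replacement."""
    if not (0 < fraction <= 1):
        raise KnowclustError(f"fraction must lie in (0, 1], got {fraction}")
    labels = check_labels(labels, expr)
    rng = np.random.default_rng(seed)
    n_keep = int(fraction * expr.n_cells)
    rows = rng.choice(expr.n_cells, size=n_keep, replace=False)
    return _subset(expr, labels, rows)
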
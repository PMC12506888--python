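"""Reading and writing of on-disk artifacts.

Dense matrices travel as TSV/CSV with one header row and a leading id column;
sparse matrices as MatrixMarket coordinate triplets plus one-name-per-line
features/barcodes files.  Results are a TSV table plus a JSON score trace.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import yaml

from .containers import ExpressionMatrix, KnowclustError, RunConfig, _duplicates


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_dense(
    path: str | Path, cells_in_rows: bool = True, modality: str = "RNA"
) -> ExpressionMatrix:
    """Read a dense TSV/CSV expression matrix.

    The file has one header row and one leading id column.  ``cells_in_rows``
    states the on-disk orientation; the returned matrix is always
    cells x features with ``state='counts'``.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dupes = _duplicates(header)
    if dupes:  # pandas silently mangles duplicate column names
        kind = "feature" if cells_in_rows else "cell"
        raise KnowclustError(f"duplicate {kind} names in {path}: {sorted(dupes)}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if not cells_in_rows:
        df = df.T
    cell_ids = [str(c) for c in df.index]
    feature_names = [str(f) for f in df.columns]
    for kind, names in (("cell", cell_ids), ("feature", feature_names)):
        dupes = _duplicates(names)
        if dupes:
            raise KnowclustError(f"duplicate {kind} names in {path}: {sorted(dupes)}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.map(lambda v: isinstance(v, str))
        rows, cols = np.nonzero(bad.to_numpy())
        r, c = int(rows[0]), int(cols[0])
        raise KnowclustError(
            f"non-numeric value {df.iat[r, c]!r} at row {cell_ids[r]!r}, "
            f"column {feature_names[c]!r} in {path}"
        )
    return ExpressionMatrix(values.astype(float), cell_ids, feature_names, modality, "counts")


def read_expression_mtx(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    modality: str = "RNA",
    cells_in_rows: bool = True,
) -> ExpressionMatrix:
    """Read a MatrixMarket triplet plus features/barcodes name files.

    On-disk indices are 1-based; absent triplets are zeros.  Pass
    ``cells_in_rows=False`` for the 10x orientation (features x cells).
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # scipy raises bare ValueError on bad indices
        raise KnowclustError(f"cannot read MatrixMarket file {matrix_path}: {exc}") from exc
    dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
    features = _read_names(features_path)
    barcodes = _read_names(barcodes_path)
    if not cells_in_rows:
        dense = dense.T
    n, p = dense.shape
    if n != len(barcodes):
        raise KnowclustError(
            f"matrix has {n} cells but {len(barcodes)} barcodes in {barcodes_path}"
        )
    if p != len(features):
        raise KnowclustError(
            f"matrix has {p} features but {len(features)} names in {features_path}"
        )
    return ExpressionMatrix(dense, barcodes, features, modality, "counts")


def _read_names(path: str | Path) -> list[str]:
    with open(path) as fh:
        names = [line.split("\t")[0].strip() for line in fh if line.strip()]
    return names


def read_labels(path: str | Path, expr: ExpressionMatrix | None = None) -> list[str]:
    """Read a label file: two-column TSV (cell_id, label) or one label per line.

    With a companion matrix, two-column files are reordered to the matrix's
    cell order and missing ids raise.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.strip():
                rows.append(line.split("\t"))
    if not rows:
        raise KnowclustError(f"empty label file {path}")
    two_col = all(len(r) >= 2 for r in rows)
    if two_col and rows[0][0] in ("cell_id", "cell", "barcode"):
        rows = rows[1:]
    if two_col:
        mapping = {r[0]: r[1] for r in rows}
        if expr is not None:
            missing = [c for c in expr.cell_ids if c not in mapping]
            if missing:
                raise KnowclustError(
                    f"label file {path} is missing cell ids: {missing[:10]}"
                )
            return [mapping[c] for c in expr.cell_ids]
        return [r[1] for r in rows]
    labels = [r[0] for r in rows]
    if expr is not None and len(labels) != expr.n_cells:
        raise KnowclustError(
            f"{len(labels)} labels in {path} for {expr.n_cells} cells"
        )
    return labels


def write_labels(labels, path: str | Path, cell_ids=None) -> None:
    with open(path, "w") as fh:
        if cell_ids is None:
            fh.write("\n".join(str(x) for x in labels) + "\n")
        else:
            for c, l in zip(cell_ids, labels):
                fh.write(f"{c}\t{l}\n")


def write_result(result, path: str | Path) -> None:
    """Write a ResultTable to TSV plus a side JSON with the score trace.

    Correlations are printed with 6 significant digits so a re-read matches
    to 1e-6.
    """
    path = Path(path)
    df = result.table
    out = df.copy()
    out["correlation"] = [float(f"{v:.6g}") for v in df["correlation"]]
    out.to_csv(path, sep="\t", index=False)
    trace_path = path.with_suffix(path.suffix + ".trace.json")
    with open(trace_path, "w") as fh:
        json.dump(
            {"selected_k": int(result.n_clusters), "score_trace": result.score_trace},
            fh, indent=1, default=_json_default,
        )


def read_result_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"cell_id": str, "matched_type": str})


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if hasattr(o, "__dict__"):
        return asdict(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; absent keys fall back to defaults, unknown keys raise."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise KnowclustError(f"config {path} must be a key-value mapping")
    unknown = set(data) - RunConfig.field_names()
    if unknown:
        raise KnowclustError(f"unknown config keys: {sorted(unknown)}")
    if "hidden_widths" in data:
        data["hidden_widths"] = tuple(data["hidden_widths"])
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    data = asdict(config)
    data["hidden_widths"] = list(config.hidden_widths)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)


def write_expression_dense(expr: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(expr.values, index=expr.cell_ids, columns=expr.feature_names)
    df.to_csv(path, sep=_sep_for(path), index_label="cell_id")
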
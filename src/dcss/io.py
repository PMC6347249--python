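"""Readers and writers for expression matrices and selection reports.

Matrices come in as MatrixMarket coordinate files (cells x features, with
optional sidecar one-id-per-line text files ``<stem>.rows.txt`` /
``<stem>.cols.txt``) or as dense CSV/TSV with a header row of feature
ids and a first column of cell ids.  Selections go out as a JSON report
with stable key order plus a plain one-index-per-line text file; indices
in machine-readable outputs are 0-based and the report says so.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .matrix import ExpressionMatrix

__all__ = ["read_matrix", "write_matrix", "write_selection_report"]


def _read_sidecar(path: Path, n: int, axis: str) -> list[str] | None:
    if not path.exists():
        return None
    ids = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    if len(ids) != n:
        raise ValueError(
            f"sidecar {path.name} has {len(ids)} ids but the matrix has {n} {axis}"
        )
    return ids


def read_matrix(
    path: str | Path,
    fmt: str | None = None,
    transpose: bool = False,
    allow_negative: bool = False,
) -> ExpressionMatrix:
    """Read a cells x features matrix from MTX, CSV or TSV.

    ``fmt`` is inferred from the suffix when omitted.  ``transpose``
    flips a features x cells dump (common in 10x-style exports) into the
    cells-as-rows orientation.  Negative entries raise unless
    ``allow_negative`` (for pre-centered input).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        suffix = path.suffix.lower().lstrip(".")
        fmt = {"mtx": "mtx", "csv": "csv", "tsv": "tsv", "txt": "tsv"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    if fmt == "mtx":
        values = sp.csr_matrix(sio.mmread(path))
        if transpose:
            values = values.T.tocsr()
        n, d = values.shape
        stem = str(path.with_suffix(""))
        cell_ids = _read_sidecar(Path(stem + ".rows.txt"), n, "rows")
        feature_ids = _read_sidecar(Path(stem + ".cols.txt"), d, "columns")
        return ExpressionMatrix(
            values,
            cell_ids=cell_ids,
            feature_ids=feature_ids,
            require_nonnegative=not allow_negative,
        )
    if fmt in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t", index_col=0)
        if df.empty and df.shape[1] == 0:
            raise ValueError(f"{path} has no data columns (malformed header?)")
        values = df.to_numpy(dtype=float)
        if transpose:
            values = values.T
            cell_ids, feature_ids = list(df.columns), list(df.index)
        else:
            cell_ids, feature_ids = list(df.index), list(df.columns)
        return ExpressionMatrix(
            values,
            cell_ids=cell_ids,
            feature_ids=feature_ids,
            require_nonnegative=not allow_negative,
        )
    raise ValueError(f"unknown format {fmt!r}")


def write_matrix(A: ExpressionMatrix, path: str | Path, fmt: str = "mtx") -> None:
    """Write a matrix as MTX (+ id sidecars) or CSV/TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        values = A.values if A.is_sparse else sp.coo_matrix(A.values)
        sio.mmwrite(path, values)
        stem = str(path.with_suffix(""))
        Path(stem + ".rows.txt").write_text(
            "\n".join(str(i) for i in A.cell_ids) + "\n"
        )
        Path(stem + ".cols.txt").write_text(
            "\n".join(str(i) for i in A.feature_ids) + "\n"
        )
    elif fmt in ("csv", "tsv"):
        df = pd.DataFrame(A.dense(), index=A.cell_ids, columns=A.feature_ids)
        df.to_csv(path, sep="," if fmt == "csv" else "\t")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_selection_report(
    selection,
    path: str | Path,
    bound_report=None,
    extra: dict | None = None,
) -> dict:
    """Write a selection as ``<path>.json`` + ``<path>.indices.txt``.

    The JSON report carries the selection parameters and verdicts with
    sorted keys for diffability; the text file is one 0-based column
    index per line in inclusion order.  Returns the report dict.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    report = dict(selection.to_dict())
    if bound_report is not None:
        report["bounds"] = bound_report.to_dict()
    if extra:
        report.update(extra)
    report["format_version"] = 1
    base = str(path.with_suffix("")) if path.suffix == ".json" else str(path)
    Path(base + ".json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    Path(base + ".indices.txt").write_text(
        "\n".join(str(int(i)) for i in report["indices"]) + "\n"
    )
    return report
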
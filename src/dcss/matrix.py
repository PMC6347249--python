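"""The cells-by-features expression matrix container.

Rows are cells, columns are features (genes, UMI-deduplicated gene counts,
or read equivalence classes); typically n_cells < n_features.  Values are
non-negative counts or normalized expression.  Dense ndarray and scipy
sparse storage are both supported; sparsity is preserved through column
subsetting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

__all__ = ["ExpressionMatrix", "center_columns"]


def _as_id_array(ids: Sequence, n: int, axis_name: str) -> np.ndarray:
    arr = np.asarray(list(ids), dtype=object)
    if arr.ndim != 1 or arr.shape[0] != n:
        raise ValueError(
            f"{axis_name} identifiers: expected {n} entries, got {arr.shape}"
        )
    if len(set(arr.tolist())) != n:
        raise ValueError(f"{axis_name} identifiers are not unique")
    return arr


@dataclass
class ExpressionMatrix:
    """An n_cells x n_features matrix with row (cell) and column (feature) ids.

    Parameters
    ----------
    values
        Dense ndarray or scipy sparse matrix, shape (n_cells, n_features).
        All entries must be finite; count data is expected non-negative
        (validation controlled by ``require_nonnegative``).
    cell_ids, feature_ids
        Unique identifiers for rows and columns.  Defaults to
        ``cell_0..`` / ``feature_0..``.
    rows_are_cells
        Orientation flag.  The selection machinery always operates on
        columns; set False (or transpose first) when filtering cells.
    """

    values: np.ndarray | sp.spmatrix
    cell_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    feature_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    rows_are_cells: bool = True
    require_nonnegative: bool = True

    def __post_init__(self) -> None:
        v = self.values
        if sp.issparse(v):
            self.values = v = v.tocsr()
            data = v.data
        else:
            self.values = v = np.asarray(v, dtype=float)
            if v.ndim != 2:
                raise ValueError(f"expected a 2-d matrix, got shape {v.shape}")
            data = v
        if data.size and not np.all(np.isfinite(data)):
            raise ValueError("matrix contains non-finite values")
        if self.require_nonnegative and data.size and data.min() < 0:
            raise ValueError("count matrix contains negative values")
        n, d = v.shape
        if self.cell_ids is None:
            self.cell_ids = np.array([f"cell_{i}" for i in range(n)], dtype=object)
        else:
            self.cell_ids = _as_id_array(self.cell_ids, n, "cell")
        if self.feature_ids is None:
            self.feature_ids = np.array(
                [f"feature_{j}" for j in range(d)], dtype=object
            )
        else:
            self.feature_ids = _as_id_array(self.feature_ids, d, "feature")

    # -- basic geometry -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def is_sparse(self) -> bool:
        return sp.issparse(self.values)

    def dense(self) -> np.ndarray:
        """Materialize the values as a dense float ndarray."""
        if self.is_sparse:
            return np.asarray(self.values.todense(), dtype=float)
        return self.values

    def column_sums(self) -> np.ndarray:
        if self.is_sparse:
            return np.asarray(self.values.sum(axis=0)).ravel()
        return self.values.sum(axis=0)

    def row_sums(self) -> np.ndarray:
        if self.is_sparse:
            return np.asarray(self.values.sum(axis=1)).ravel()
        return self.values.sum(axis=1)

    def transpose(self) -> "ExpressionMatrix":
        """Swap cells and features (for filtering cells when n > d)."""
        return ExpressionMatrix(
            self.values.T,
            cell_ids=self.feature_ids,
            feature_ids=self.cell_ids,
            rows_are_cells=not self.rows_are_cells,
            require_nonnegative=self.require_nonnegative,
        )


def center_columns(A: ExpressionMatrix) -> tuple[ExpressionMatrix, np.ndarray]:
    """Subtract the column-means vector mu = (1/n) A^T 1 from every row.

    Returns the mean-centered matrix (dense — centering destroys sparsity)
    and mu.  Centering is optional in the selection workflow: the case of
    raw counts is the default, centering gives the empirical-variance
    reading of the Frobenius bound.
    """
    dense = A.dense()
    mu = dense.mean(axis=0)
    centered = ExpressionMatrix(
        dense - mu,
        cell_ids=A.cell_ids,
        feature_ids=A.feature_ids,
        rows_are_cells=A.rows_are_cells,
        require_nonnegative=False,
    )
    return centered, mu
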
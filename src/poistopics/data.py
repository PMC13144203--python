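"""Sparse count-matrix container shared by Poisson NMF and the topic model.

The observed data for both models is an n x m matrix of non-negative integer
counts: documents x terms in text corpora, cells x genes in single-cell
RNA-seq. Real corpora are overwhelmingly sparse (often well under 10%
nonzero), so the canonical storage is compressed sparse; dense arrays are
accepted on input and produced only as explicit views.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["CountMatrix", "DataError", "validate_counts", "drop_empty"]

#: entries must be within this distance of an integer to be accepted
INTEGER_TOL = 1e-9


class DataError(ValueError):
    """Input counts violate the models' requirements."""


class CountMatrix:
    """Non-negative integer count matrix stored in compressed sparse form.

    Parameters
    ----------
    matrix : array-like or scipy sparse matrix
        Counts. Real-valued entries are accepted only if each is within
        ``1e-9`` of an integer, and are rounded. Negative, non-finite or
        genuinely fractional entries raise :class:`DataError`.
    """

    def __init__(self, matrix) -> None:
        if isinstance(matrix, CountMatrix):
            coo = matrix.csr.tocoo()
        elif sp.issparse(matrix):
            coo = matrix.tocoo()
        else:
            arr = np.asarray(matrix, dtype=float)
            if arr.ndim != 2:
                raise DataError("counts must form a 2-d matrix")
            coo = sp.coo_matrix(arr)
        if coo.shape[0] < 1 or coo.shape[1] < 1:
            raise DataError("count matrix must have at least one row and one column")
        data = np.asarray(coo.data, dtype=float)
        if data.size:
            bad = ~np.isfinite(data)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise DataError(
                    f"non-finite count at (row {int(coo.row[i])}, column {int(coo.col[i])})"
                )
            if (data < 0).any():
                i = int(np.flatnonzero(data < 0)[0])
                raise DataError(
                    f"negative count {data[i]!r} at "
                    f"(row {int(coo.row[i])}, column {int(coo.col[i])})"
                )
            rounded = np.rint(data)
            off = np.abs(data - rounded) > INTEGER_TOL
            if off.any():
                i = int(np.flatnonzero(off)[0])
                raise DataError(
                    f"non-integer count {data[i]!r} at "
                    f"(row {int(coo.row[i])}, column {int(coo.col[i])})"
                )
            data = rounded
        csr = sp.csr_matrix((data, (coo.row, coo.col)), shape=coo.shape)
        csr.sum_duplicates()
        csr.eliminate_zeros()
        if csr.nnz == 0:
            raise DataError("count matrix has no nonzero entries")
        self._csr: sp.csr_matrix = csr
        self._csc: sp.csc_matrix | None = None
        self._triplets: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    # ------------------------------------------------------------------
    # basic descriptors
    @property
    def shape(self) -> tuple[int, int]:
        return self._csr.shape

    @property
    def n(self) -> int:
        """Number of rows (documents / cells)."""
        return self._csr.shape[0]

    @property
    def m(self) -> int:
        """Number of columns (terms / genes)."""
        return self._csr.shape[1]

    @property
    def nnz(self) -> int:
        return self._csr.nnz

    @property
    def row_sums(self) -> np.ndarray:
        """Per-row totals t_i = sum_j x_ij."""
        return np.asarray(self._csr.sum(axis=1)).ravel()

    @property
    def col_sums(self) -> np.ndarray:
        return np.asarray(self._csr.sum(axis=0)).ravel()

    @property
    def csr(self) -> sp.csr_matrix:
        return self._csr

    @property
    def csc(self) -> sp.csc_matrix:
        if self._csc is None:
            self._csc = self._csr.tocsc()
        return self._csc

    def triplets(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Stored nonzeros as ``(rows, cols, values)`` in row-major order."""
        if self._triplets is None:
            coo = self._csr.tocoo()
            self._triplets = (
                coo.row.copy(),
                coo.col.copy(),
                np.asarray(coo.data, dtype=float).copy(),
            )
        return self._triplets

    def toarray(self) -> np.ndarray:
        """Dense view of the counts (never the canonical form)."""
        return self._csr.toarray()

    def transpose(self) -> "CountMatrix":
        return CountMatrix(self._csr.T)

    @property
    def T(self) -> "CountMatrix":
        return self.transpose()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CountMatrix({self.n}x{self.m}, nnz={self.nnz})"


def validate_counts(X: CountMatrix) -> list[str]:
    """Report degenerate structure in a count matrix.

    Returns a list of human-readable warnings, one per all-zero row and one
    per all-zero column. The fitting driver treats these as errors (an
    all-zero row or column admits no meaningful loading/factor estimate);
    this function only reports. Row/column indices are 0-based.
    """
    warnings: list[str] = []
    for i in np.flatnonzero(X.row_sums == 0):
        warnings.append(f"row {int(i)} is all zero (t_{int(i)} = 0)")
    for j in np.flatnonzero(X.col_sums == 0):
        warnings.append(f"column {int(j)} is all zero")
    return warnings


def drop_empty(X: CountMatrix) -> tuple[CountMatrix, np.ndarray, np.ndarray]:
    """Remove all-zero rows and columns.

    Returns the filtered matrix together with the retained row and column
    indices, so ground-truth factor matrices can be subset to match.
    """
    rows = np.flatnonzero(X.row_sums > 0)
    cols = np.flatnonzero(X.col_sums > 0)
    if rows.size == X.n and cols.size == X.m:
        return X, rows, cols
    sub = X.csr[rows][:, cols]
    return CountMatrix(sub), rows, cols
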
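"""Data containers for clustering.

Objects to be clustered are rows; features are columns. A matrix is
either *continuous* (expression-type measurements, real-valued) or
*genotype* (biallelic SNP genotypes coded 0 = homozygous reference,
1 = heterozygous, 2 = homozygous alternative). Missing values are a
load-time error; containers never hold NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CONTINUOUS = "continuous"
GENOTYPE = "genotype"

_KINDS = (CONTINUOUS, GENOTYPE)


class MatrixError(ValueError):
    """Raised for malformed or out-of-contract data matrices."""


@dataclass(frozen=True)
class DataMatrix:
    """A rectangular objects x features matrix.

    Parameters
    ----------
    values
        2-D array, one row per object. Continuous matrices are stored as
        float64, genotype matrices as small integers restricted to {0,1,2}.
    kind
        ``"continuous"`` or ``"genotype"``.
    row_ids
        Optional object identifiers, one per row.
    """

    values: np.ndarray
    kind: str = CONTINUOUS
    row_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise MatrixError(f"unknown matrix kind {self.kind!r}")
        values = np.asarray(self.values)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise MatrixError(
                f"expected a non-empty 2-D matrix, got shape {values.shape}"
            )
        if self.kind == CONTINUOUS:
            values = values.astype(np.float64, copy=False)
            if not np.all(np.isfinite(values)):
                i, j = np.argwhere(~np.isfinite(values))[0]
                raise MatrixError(
                    f"non-finite value at row {i + 1}, column {j + 1}"
                )
        else:
            if not np.issubdtype(values.dtype, np.integer):
                as_int = np.asarray(values).astype(np.int64, copy=True)
                if not np.array_equal(as_int, np.asarray(values, dtype=float)):
                    raise MatrixError("genotype matrix has non-integer entries")
                values = as_int
            bad = (values < 0) | (values > 2)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise MatrixError(
                    f"genotype out of range {{0,1,2}} at row {i + 1}, "
                    f"column {j + 1}: {values[i, j]}"
                )
            values = values.astype(np.int64, copy=False)
        object.__setattr__(self, "values", values)
        if self.row_ids is not None:
            ids = np.asarray(self.row_ids)
            if ids.shape != (values.shape[0],):
                raise MatrixError(
                    f"row_ids length {ids.shape} does not match "
                    f"{values.shape[0]} rows"
                )
            object.__setattr__(self, "row_ids", ids)

    @property
    def n_rows(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_cols(self) -> int:
        return int(self.values.shape[1])

    def transposed(self) -> "DataMatrix":
        """Swap objects and features (e.g. cluster genes instead of arrays)."""
        return DataMatrix(self.values.T.copy(), kind=self.kind)

    def take_rows(self, indices: np.ndarray) -> "DataMatrix":
        ids = None if self.row_ids is None else self.row_ids[indices]
        return DataMatrix(self.values[indices], kind=self.kind, row_ids=ids)
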
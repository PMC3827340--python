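"""Column standardization (z-scoring) of factor and response matrices.

Both the dose (factor) matrix and the endpoint (response) matrix are mapped
column-wise to mean 0, standard deviation 1 before modelling; the stored
means/SDs support the exact inverse map.  Sample SD (n-1 denominator) is
used.  Missing values are rejected rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["StandardizedMatrix", "zscore"]


@dataclass
class StandardizedMatrix:
    values: np.ndarray           # n x p, each column mean 0, sd 1
    column_means: np.ndarray     # p
    column_sds: np.ndarray       # p
    column_names: list[str]

    def transform(self, new: np.ndarray) -> np.ndarray:
        """Standardize new rows with the stored training means/SDs."""
        new = np.atleast_2d(np.asarray(new, dtype=float))
        if new.shape[1] != len(self.column_means):
            raise ValueError(
                f"expected {len(self.column_means)} columns, got {new.shape[1]}"
            )
        return (new - self.column_means) / self.column_sds

    def inverse(self, values: np.ndarray | None = None) -> np.ndarray:
        """Map standardized values back to the original scale."""
        v = self.values if values is None else np.asarray(values, dtype=float)
        return v * self.column_sds + self.column_means


def zscore(
    matrix: np.ndarray | pd.DataFrame,
    names: Sequence[str] | None = None,
    ddof: int = 1,
) -> StandardizedMatrix:
    """Standardize each column to mean 0 and (sample) standard deviation 1.

    Raises on fewer than two rows, non-finite cells, or a constant column
    (named in the error) because a zero-variance column cannot be scaled.
    """
    if isinstance(matrix, pd.DataFrame):
        if names is None:
            names = [str(c) for c in matrix.columns]
        matrix = matrix.to_numpy(dtype=float)
    X = np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 rows to standardize")
    if not np.isfinite(X).all():
        raise ValueError("matrix contains missing or non-finite values")
    if names is None:
        names = [f"x{j + 1}" for j in range(p)]
    names = list(names)

    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=ddof)
    for j, s in enumerate(sds):
        if s == 0:
            raise ValueError(f"zero variance in column {names[j]!r}")
    return StandardizedMatrix((X - means) / sds, means, sds, names)
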
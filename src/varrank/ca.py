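"""Correspondence analysis of the three-group VAF contingency table.

Implemented from first principles: the matrix of standardized chi-square
residuals is decomposed by SVD and principal coordinates are recovered by
rescaling singular vectors with the row/column masses. The per-axis sign is
fixed so the resistant-group column loads nonnegatively, making runs
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .datamodel import ContingencyTable
from .errors import ValidationError

__all__ = ["CaSolution", "correspondence_analysis", "project"]

#: singular values below this are treated as zero (rank-deficient axes)
_SV_TOL = 1e-12


@dataclass
class CaSolution:
    """Principal-coordinate decomposition of a contingency table."""

    row_coords: pd.DataFrame  # rows x dims
    col_coords: pd.DataFrame  # columns x dims
    singular_values: np.ndarray
    total_inertia: float
    row_masses: pd.Series
    col_masses: pd.Series

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.singular_values**2

    @property
    def explained(self) -> np.ndarray:
        """Fraction of total inertia carried by each axis."""
        if self.total_inertia == 0:
            return np.zeros_like(self.singular_values)
        return self.eigenvalues / self.total_inertia

    @property
    def n_dims(self) -> int:
        return len(self.singular_values)


def _as_frame(table: Union[ContingencyTable, pd.DataFrame, np.ndarray]) -> pd.DataFrame:
    if isinstance(table, ContingencyTable):
        return table.data
    if isinstance(table, np.ndarray):
        return pd.DataFrame(table)
    return table


def correspondence_analysis(
    table: Union[ContingencyTable, pd.DataFrame, np.ndarray],
    sign_column: Optional[str] = "VAF_resistant",
) -> CaSolution:
    """Decompose a nonnegative table into principal coordinates.

    With P the table divided by its grand total, row masses r and column
    masses c, the standardized residuals S_ij = (P_ij - r_i c_j) / sqrt(r_i c_j)
    are SVD-factored; row principal coordinates are U * sigma scaled by
    1/sqrt(r), column coordinates V * sigma scaled by 1/sqrt(c). The total
    inertia sum(sigma^2) equals the table's chi-square statistic over its
    grand total.
    """
    frame = _as_frame(table).astype(float)
    values = frame.to_numpy()
    if values.size == 0:
        raise ValidationError("cannot analyze an empty table")
    if (values < 0).any():
        raise ValidationError("table entries must be nonnegative")
    total = values.sum()
    if total <= 0:
        raise ValidationError("table grand total must be positive")
    row_sums = values.sum(axis=1)
    col_sums = values.sum(axis=0)
    if (row_sums == 0).any():
        bad = frame.index[np.flatnonzero(row_sums == 0)[0]]
        raise ValidationError(f"all-zero row {bad!r}; prune before analysis")
    if (col_sums == 0).any():
        bad = frame.columns[np.flatnonzero(col_sums == 0)[0]]
        raise ValidationError(f"all-zero column {bad!r}")

    P = values / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    expected = np.outer(r, c)
    S = (P - expected) / np.sqrt(expected)
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)

    max_dims = min(values.shape) - 1
    keep = sv > _SV_TOL
    keep[max_dims:] = False
    U, sv, V = U[:, keep], sv[keep], Vt[keep, :].T

    row_coords = (U * sv) / np.sqrt(r)[:, None]
    col_coords = (V * sv) / np.sqrt(c)[:, None]

    # deterministic axis signs: chosen column loads >= 0 on every axis
    if sign_column is not None and sign_column in frame.columns:
        ref = list(frame.columns).index(sign_column)
    else:
        ref = int(np.argmax(c))
    flip = col_coords[ref, :] < 0
    row_coords[:, flip] *= -1
    col_coords[:, flip] *= -1

    dims = [f"dim{k + 1}" for k in range(sv.size)]
    return CaSolution(
        row_coords=pd.DataFrame(row_coords, index=frame.index, columns=dims),
        col_coords=pd.DataFrame(col_coords, index=frame.columns, columns=dims),
        singular_values=sv,
        total_inertia=float((sv**2).sum()),
        row_masses=pd.Series(r, index=frame.index),
        col_masses=pd.Series(c, index=frame.columns),
    )


def project(solution: CaSolution, dims: int = 2) -> pd.DataFrame:
    """First `dims` row principal coordinates, zero-padded past the table rank."""
    coords = solution.row_coords
    if coords.shape[1] >= dims:
        return coords.iloc[:, :dims].copy()
    out = coords.copy()
    for k in range(coords.shape[1], dims):
        out[f"dim{k + 1}"] = 0.0
    return out
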
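"""Pianka niche-overlap index over utilization matrices.

The Pianka index between two resource-utilization vectors u and v is

    O(u, v) = sum_k p_k q_k / sqrt(sum_k p_k^2 * sum_k q_k^2)

where p and q are u and v normalized to sum to one.  O is symmetric, lies in
[0, 1], equals 1 for proportional vectors (identical resource use) and 0 for
disjoint supports (complete partitioning).  Community-level overlap is the
arithmetic mean of O over all unordered row pairs of a species x resource
matrix (trophic: plants as resource states; diel: hour bins as resource
states).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["pianka_pair", "pairwise_pianka", "mean_overlap", "OverlapResult", "PiankaOverlap"]


def _as_matrix(matrix) -> tuple[np.ndarray, list]:
    if isinstance(matrix, pd.DataFrame):
        return matrix.to_numpy(dtype=float), list(matrix.index)
    arr = np.asarray(matrix, dtype=float)
    return arr, list(range(arr.shape[0]))


def _validate_rows(arr: np.ndarray, labels: list) -> None:
    if np.any(arr < 0):
        raise ValueError("utilization values must be non-negative")
    sums = arr.sum(axis=1)
    bad = [labels[i] for i in np.flatnonzero(sums <= 0)]
    if bad:
        raise ValueError(f"rows with zero total utilization (overlap undefined): {bad}")


def pianka_pair(u, v) -> float:
    """Pianka overlap between two utilization vectors.

    Invariant to rescaling either vector by a positive constant; symmetric in
    its arguments.  Raises for negative entries or zero-sum vectors.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("u and v must be 1-D vectors of the same length")
    arr = np.vstack([u, v])
    _validate_rows(arr, ["u", "v"])
    p = u / u.sum()
    q = v / v.sum()
    return float((p * q).sum() / np.sqrt((p * p).sum() * (q * q).sum()))


def _pianka_all_pairs(arr: np.ndarray) -> np.ndarray:
    """Full symmetric Pianka matrix for the rows of `arr` (validated input)."""
    p = arr / arr.sum(axis=1, keepdims=True)
    num = p @ p.T
    ss = np.einsum("ik,ik->i", p, p)
    return num / np.sqrt(np.outer(ss, ss))


def pairwise_pianka(matrix) -> pd.DataFrame:
    """Long-form table (row_a, row_b, pianka) over all unordered row pairs."""
    arr, labels = _as_matrix(matrix)
    _validate_rows(arr, labels)
    omat = _pianka_all_pairs(arr)
    ia, ib = np.triu_indices(arr.shape[0], k=1)
    return pd.DataFrame(
        {
            "row_a": [labels[i] for i in ia],
            "row_b": [labels[j] for j in ib],
            "pianka": omat[ia, ib],
        }
    )


@dataclass
class OverlapResult:
    """Pairwise Pianka values and their community mean for one matrix."""

    pair_values: pd.DataFrame
    mean_value: float
    matrix_id: str = ""
    n_rows: int = 0

    def pair_lookup(self) -> dict[frozenset, float]:
        return {
            frozenset((a, b)): v
            for a, b, v in self.pair_values[["row_a", "row_b", "pianka"]].itertuples(index=False)
        }


class PiankaOverlap(BaseEstimator):
    """Mean pairwise Pianka overlap of a utilization matrix.

    sklearn-style estimator: ``fit(X)`` computes, for a species x resource
    matrix ``X`` (DataFrame or array, >= 2 rows with positive sums), all
    N(N-1)/2 pairwise index values and their arithmetic mean.

    Attributes
    ----------
    pair_values_ : pd.DataFrame
        Columns ``row_a``, ``row_b``, ``pianka``.
    mean_ : float
        Mean over all unordered pairs.
    n_rows_ : int
    """

    def __init__(self, matrix_id: str = ""):
        self.matrix_id = matrix_id

    def fit(self, X, y=None):
        arr, labels = _as_matrix(X)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least two rows")
        _validate_rows(arr, labels)
        self.pair_values_ = pairwise_pianka(X)
        self.mean_ = float(self.pair_values_["pianka"].mean())
        self.n_rows_ = arr.shape[0]
        return self

    def result(self) -> OverlapResult:
        return OverlapResult(
            pair_values=self.pair_values_,
            mean_value=self.mean_,
            matrix_id=self.matrix_id,
            n_rows=self.n_rows_,
        )


def mean_overlap(matrix, matrix_id: str = "") -> OverlapResult:
    """Mean pairwise Pianka overlap (functional wrapper over PiankaOverlap)."""
    return PiankaOverlap(matrix_id=matrix_id).fit(matrix).result()
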
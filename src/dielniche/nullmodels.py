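"""Randomization null models for niche-overlap tests.

Two randomizers are provided:

* **RA3** — each row's entries are independently and uniformly permuted across
  columns.  Row multisets (hence niche breadth and row totals) are preserved;
  any resource state can be used.  Appropriate for trophic (species x plant)
  matrices.
* **ROSARIO** — each row is circularly shifted along the ordered time axis by
  an integer offset drawn uniformly over the number of bins.  The within-row
  sequence (the shape of the diel activity curve, including its temporal
  autocorrelation) is preserved up to rotation; only its location in the time
  domain changes.  Appropriate for diel (species x hour-bin) matrices.

The Monte-Carlo test compares the observed mean pairwise Pianka overlap with
the distribution of null means.  One-tailed probabilities:

* ``p_partitioning`` — proportion of null means **at least** the observed mean,
  i.e. randomizations showing at most the observed amount of partitioning.  A
  small value indicates significant niche partitioning.
* ``p_overlap`` — proportion of null means at most the observed mean; small
  values indicate significantly coincident (aggregated) resource use.

Ties count toward both tails, so the two probabilities sum to at least one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .overlap import _as_matrix, _pianka_all_pairs, _validate_rows

__all__ = ["ra3_randomize", "rosario_randomize", "NullModelTest", "NullTestResult", "null_model_test"]


def _wrap_like(arr: np.ndarray, template) -> np.ndarray | pd.DataFrame:
    if isinstance(template, pd.DataFrame):
        return pd.DataFrame(arr, index=template.index, columns=template.columns)
    return arr


def ra3_randomize(matrix, rng: np.random.Generator):
    """Independently permute each row's entries across columns (RA3)."""
    arr, _ = _as_matrix(matrix)
    out = np.empty_like(arr)
    for i in range(arr.shape[0]):
        out[i] = arr[i, rng.permutation(arr.shape[1])]
    return _wrap_like(out, matrix)


def _nonwrap_offset_bounds(row: np.ndarray) -> tuple[int, int]:
    """Range [lo, hi] of shifts keeping the row's support inside the domain."""
    support = np.flatnonzero(row)
    if support.size == 0:
        return 0, 0
    return -int(support[0]), int(row.size - 1 - support[-1])


def rosario_randomize(matrix, rng: np.random.Generator, wrap: bool = True, coupled: bool = False):
    """Shift each row's diel pattern along the time axis (ROSARIO).

    ``wrap=True`` (default) rotates circularly, which preserves the pattern
    shape exactly for every offset.  ``wrap=False`` draws, per row, only
    offsets that keep the nonzero support inside the domain (no mass is lost).
    ``coupled=True`` applies one common offset to every row — a degenerate
    variant kept for sensitivity analysis, since a common rotation leaves all
    pairwise overlaps unchanged.
    """
    arr, _ = _as_matrix(matrix)
    n, k = arr.shape
    if k == 1:
        warnings.warn("single-column matrix: ROSARIO randomization is the identity")
        return _wrap_like(arr.copy(), matrix)
    out = np.empty_like(arr)
    if wrap:
        if coupled:
            offsets = np.full(n, rng.integers(k))
        else:
            offsets = rng.integers(k, size=n)
        for i in range(n):
            out[i] = np.roll(arr[i], offsets[i])
    else:
        for i in range(n):
            lo, hi = _nonwrap_offset_bounds(arr[i])
            out[i] = np.roll(arr[i], int(rng.integers(lo, hi + 1)))
    return _wrap_like(out, matrix)


def _batch_null_means(
    arr: np.ndarray,
    model: str,
    n_reps: int,
    rng: np.random.Generator,
    wrap: bool = True,
    coupled: bool = False,
    batch: int = 2000,
) -> np.ndarray:
    """Vectorized null distribution of the mean pairwise Pianka index."""
    n, k = arr.shape
    iu = np.triu_indices(n, k=1)
    means = np.empty(n_reps)
    done = 0
    while done < n_reps:
        b = min(batch, n_reps - done)
        if model == "ra3":
            keys = rng.random((b, n, k))
            idx = np.argsort(keys, axis=2)
            null = np.take_along_axis(np.broadcast_to(arr, (b, n, k)), idx, axis=2)
        elif model == "rosario":
            if k == 1:
                null = np.broadcast_to(arr, (b, n, k)).copy()
            else:
                cols = np.arange(k)
                if wrap:
                    if coupled:
                        offs = np.repeat(rng.integers(k, size=(b, 1)), n, axis=1)
                    else:
                        offs = rng.integers(k, size=(b, n))
                else:
                    offs = np.empty((b, n), dtype=int)
                    for i in range(n):
                        lo, hi = _nonwrap_offset_bounds(arr[i])
                        offs[:, i] = rng.integers(lo, hi + 1, size=b)
                src = (cols[None, None, :] - offs[:, :, None]) % k
                null = np.take_along_axis(np.broadcast_to(arr, (b, n, k)), src, axis=2)
        else:
            raise ValueError(f"unknown null model {model!r} (expected 'ra3' or 'rosario')")
        p = null / null.sum(axis=2, keepdims=True)
        num = np.einsum("rik,rjk->rij", p, p)
        ss = np.einsum("rik,rik->ri", p, p)
        omat = num / np.sqrt(ss[:, :, None] * ss[:, None, :])
        means[done : done + b] = omat[:, iu[0], iu[1]].mean(axis=1)
        done += b
    return means


@dataclass
class NullTestResult:
    """Observed mean Pianka overlap against a randomization null."""

    observed_mean: float
    null_means: np.ndarray
    p_partitioning: float
    p_overlap: float
    model: str
    n_reps: int
    seed: int | None = None

    def summary(self) -> dict:
        return {
            "model": self.model,
            "observed_mean": self.observed_mean,
            "null_mean": float(np.mean(self.null_means)),
            "p_partitioning": self.p_partitioning,
            "p_overlap": self.p_overlap,
            "n_reps": self.n_reps,
            "seed": self.seed,
        }


class NullModelTest(BaseEstimator):
    """One-tailed Monte-Carlo test of mean Pianka overlap against a null model.

    Parameters
    ----------
    model : {'ra3', 'rosario'}
        Row-shuffle (trophic) or row time-shift (diel) randomization.
    n_reps : int, default 10000
        Number of randomized matrices.
    random_state : int or None
        Seed for the randomization stream.
    wrap : bool, default True
        ROSARIO only — circular (wrap-around) shifting.
    coupled_offsets : bool, default False
        ROSARIO only — one common offset for all rows per replicate.

    Attributes
    ----------
    observed_mean_ : float
    null_means_ : ndarray of shape (n_reps,)
    p_partitioning_ : float
        Proportion of null means >= observed (evidence for partitioning when
        small).
    p_overlap_ : float
        Proportion of null means <= observed.
    """

    def __init__(
        self,
        model: str = "ra3",
        n_reps: int = 10_000,
        random_state: int | None = None,
        wrap: bool = True,
        coupled_offsets: bool = False,
    ):
        self.model = model
        self.n_reps = n_reps
        self.random_state = random_state
        self.wrap = wrap
        self.coupled_offsets = coupled_offsets

    def fit(self, X, y=None):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        arr, labels = _as_matrix(X)
        _validate_rows(arr, labels)
        rng = np.random.default_rng(self.random_state)
        omat = _pianka_all_pairs(arr)
        iu = np.triu_indices(arr.shape[0], k=1)
        self.observed_mean_ = float(omat[iu].mean())
        self.null_means_ = _batch_null_means(
            arr, self.model, self.n_reps, rng, wrap=self.wrap, coupled=self.coupled_offsets
        )
        self.p_partitioning_ = float((self.null_means_ >= self.observed_mean_).mean())
        self.p_overlap_ = float((self.null_means_ <= self.observed_mean_).mean())
        return self

    def result(self) -> NullTestResult:
        return NullTestResult(
            observed_mean=self.observed_mean_,
            null_means=self.null_means_,
            p_partitioning=self.p_partitioning_,
            p_overlap=self.p_overlap_,
            model=self.model,
            n_reps=self.n_reps,
            seed=self.random_state,
        )


def null_model_test(matrix, model: str, n_reps: int = 10_000, seed: int | None = None, **kwargs) -> NullTestResult:
    """Functional wrapper over :class:`NullModelTest`."""
    est = NullModelTest(model=model, n_reps=n_reps, random_state=seed, **kwargs)
    return est.fit(matrix).result()
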
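"""Plant-level group comparisons and the trait-schedule Mantel test.

Each unordered plant pair is classified by whether the two species co-flowered
(shared at least one flowering month) and whether they shared at least one
hummingbird visitor (some hummingbird with positive visit counts to both in
the trophic matrix).  Diel partitioning of the pollinator niche (the pairwise
Pianka value from the resource-availability matrix M3) is then compared
between groups with a one-tailed Wilcoxon rank-sum test, under the
competition expectation that the focal (co-flowering / sharing) group shows
*lower* overlap.

The Mantel test relates pairwise dissimilarity in anther height to pairwise
dissimilarity in the hourly nectar-production schedule, one-tailed for a
positive association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu

from .overlap import OverlapResult

__all__ = [
    "classify_pairs",
    "wilcoxon_group_test",
    "mantel_test",
    "build_distance_matrices",
    "GroupTestResult",
    "MantelResult",
]


def classify_pairs(m1: pd.DataFrame, phenology: dict, m3_overlaps: OverlapResult) -> pd.DataFrame:
    """One record per unordered plant pair with group flags and Pianka value.

    Parameters
    ----------
    m1 : hummingbird x plant visit-count matrix.
    phenology : mapping plant -> set of flowering months.
    m3_overlaps : pairwise Pianka result over the plant availability matrix.
    """
    plants = list(m1.columns)
    offenders = sorted(set(plants) ^ set(phenology))
    if offenders:
        raise ValueError(f"plant labels disagree between M1 and phenology: {offenders}")
    lookup = m3_overlaps.pair_lookup()
    overlap_labels = {lab for pair in lookup for lab in pair}
    offenders = sorted(set(plants) ^ overlap_labels)
    if offenders:
        raise ValueError(f"plant labels disagree between M1 and M3 overlaps: {offenders}")
    counts = m1.to_numpy()
    records = []
    for a, b in combinations(plants, 2):
        ia, ib = plants.index(a), plants.index(b)
        records.append(
            {
                "plant_a": a,
                "plant_b": b,
                "co_flowered": bool(set(phenology[a]) & set(phenology[b])),
                "shared_pollinator": bool(np.any((counts[:, ia] > 0) & (counts[:, ib] > 0))),
                "pianka": lookup[frozenset((a, b))],
            }
        )
    return pd.DataFrame(records)


@dataclass
class GroupTestResult:
    """One-tailed rank-sum comparison of Pianka values between two groups."""

    W: float
    p: float
    n_true: int
    n_false: int
    grouping: str
    alternative: str = "less"  # focal (True) group expected to overlap less


def wilcoxon_group_test(pairs: pd.DataFrame, grouping: str) -> GroupTestResult:
    """Wilcoxon rank-sum test of pairwise Pianka values between groups.

    ``grouping`` is ``'co_flowered'`` or ``'shared_pollinator'``.  One-tailed
    with alternative "the True group has lower Pianka values" (more diel
    partitioning among co-flowering / pollinator-sharing pairs).  W follows
    the rank-sum convention of R's ``wilcox.test`` (the Mann-Whitney U of the
    focal group); ties are handled by mid-ranks with the tie-corrected normal
    approximation when exact enumeration is infeasible.
    """
    if grouping not in ("co_flowered", "shared_pollinator"):
        raise ValueError(f"unknown grouping {grouping!r}")
    flag = pairs[grouping].astype(bool)
    x = pairs.loc[flag, "pianka"].to_numpy(dtype=float)
    y = pairs.loc[~flag, "pianka"].to_numpy(dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError(f"grouping {grouping!r} leaves an empty group ({x.size} vs {y.size})")
    stat, p = mannwhitneyu(x, y, alternative="less", method="auto")
    return GroupTestResult(W=float(stat), p=float(p), n_true=x.size, n_false=y.size, grouping=grouping)


@dataclass
class MantelResult:
    """Matrix correlation between two distance matrices."""

    r: float
    p: float
    n_perm: int
    degenerate: bool = False


def _check_distance_matrix(d: pd.DataFrame, name: str) -> np.ndarray:
    arr = np.asarray(d, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{name} is not square")
    if not np.allclose(arr, arr.T):
        raise ValueError(f"{name} is not symmetric")
    if not np.allclose(np.diag(arr), 0):
        raise ValueError(f"{name} has a non-zero diagonal")
    return arr


def mantel_test(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> MantelResult:
    """One-tailed permutation Mantel test (positive association).

    r is the Pearson correlation over upper-triangle entries; p is the
    proportion of joint row/column label permutations of ``d2`` whose r is at
    least the observed one.  Zero variance in either matrix gives a flagged
    degenerate result rather than an error.
    """
    a1 = _check_distance_matrix(d1, "d1")
    a2 = _check_distance_matrix(d2, "d2")
    if a1.shape != a2.shape:
        raise ValueError("distance matrices differ in size")
    if isinstance(d1, pd.DataFrame) and isinstance(d2, pd.DataFrame):
        if list(d1.index) != list(d2.index):
            raise ValueError("distance matrices have mismatched labels")
    n = a1.shape[0]
    iu = np.triu_indices(n, k=1)
    x = a1[iu]
    if x.std() == 0 or a2[iu].std() == 0:
        warnings.warn("zero variance in a distance matrix: Mantel r undefined")
        return MantelResult(r=float("nan"), p=float("nan"), n_perm=0, degenerate=True)
    rng = np.random.default_rng(seed)

    def _corr(mat: np.ndarray) -> float:
        return float(np.corrcoef(x, mat[iu])[0, 1])

    r_obs = _corr(a2)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _corr(a2[np.ix_(perm, perm)]) >= r_obs - 1e-12:
            count += 1
    return MantelResult(r=r_obs, p=count / n_perm, n_perm=n_perm)


def build_distance_matrices(
    anther_heights: pd.Series | dict,
    hourly_production: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Anther-height and nectar-schedule dissimilarity matrices.

    Anther distance is |h_i - h_j| (cm); schedule distance is the Euclidean
    distance between per-flower hourly production vectors (rows of
    ``hourly_production``, plants x hours, mg).  Pass abundance-scaled rows to
    switch to an availability-based distance.
    """
    heights = pd.Series(anther_heights, dtype=float)
    missing = sorted(set(heights.index) ^ set(hourly_production.index))
    if missing:
        raise ValueError(f"plant sets disagree between traits and schedules: {missing}")
    plants = list(hourly_production.index)
    heights = heights.reindex(plants)
    d_anther = pd.DataFrame(
        np.abs(heights.to_numpy()[:, None] - heights.to_numpy()[None, :]),
        index=plants,
        columns=plants,
    )
    d_nectar = pd.DataFrame(
        squareform(pdist(hourly_production.to_numpy(dtype=float))),
        index=plants,
        columns=plants,
    )
    return d_anther, d_nectar
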
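"""Pair classification, Wilcoxon group tests and the Mantel test."""

from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pytest

from dielniche.group_stats import (
    GroupTestResult,
    build_distance_matrices,
    classify_pairs,
    mantel_test,
    wilcoxon_group_test,
)
from dielniche.overlap import mean_overlap


def fake_overlaps(plants, value=0.5):
    rows = [
        {"row_a": a, "row_b": b, "pianka": value} for a, b in combinations(plants, 2)
    ]
    from dielniche.overlap import OverlapResult

    return OverlapResult(pair_values=pd.DataFrame(rows), mean_value=value)


class TestClassifyPairs:
    def test_pair_count_and_sharing(self, visit_matrix):
        plants = list(visit_matrix.columns)
        phen = {p: {"2019-01"} for p in plants}
        pairs = classify_pairs(visit_matrix, phen, fake_overlaps(plants))
        assert len(pairs) == 66
        assert int(pairs["shared_pollinator"].sum()) == 57

    def test_sharing_matches_double_loop_oracle(self):
        rng = np.random.default_rng(21)
        m1 = pd.DataFrame(
            rng.integers(0, 2, size=(5, 8)) * rng.integers(1, 6, size=(5, 8)),
            index=[f"h{i}" for i in range(5)],
            columns=[f"p{j}" for j in range(8)],
        )
        plants = list(m1.columns)
        pairs = classify_pairs(m1, {p: {"m"} for p in plants}, fake_overlaps(plants))
        for row in pairs.itertuples():
            shared = any(
                m1.loc[h, row.plant_a] > 0 and m1.loc[h, row.plant_b] > 0 for h in m1.index
            )
            assert row.shared_pollinator == shared

    def test_disjoint_months_do_not_co_flower(self):
        m1 = pd.DataFrame([[1, 1]], index=["h"], columns=["a", "b"])
        pairs = classify_pairs(
            m1, {"a": {"2019-01"}, "b": {"2019-02"}}, fake_overlaps(["a", "b"])
        )
        assert not pairs["co_flowered"].iloc[0]

    def test_label_mismatch_lists_offenders(self, visit_matrix):
        phen = {p: {"m"} for p in list(visit_matrix.columns)[:-1]}
        with pytest.raises(ValueError, match="Vriesea simplex"):
            classify_pairs(visit_matrix, phen, fake_overlaps(list(visit_matrix.columns)))


def rank_sum_oracle(x, y):
    """Exhaustive one-tailed ('x lower') rank-sum p over all assignments."""
    pooled = list(x) + list(y)
    n = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()  # mid-ranks for ties
    obs = ranks[:n].sum()
    count = total = 0
    for idx in combinations(range(len(pooled)), n):
        total += 1
        if ranks[list(idx)].sum() <= obs:
            count += 1
    return count / total


class TestWilcoxon:
    def pairs_frame(self, x, y, grouping="co_flowered"):
        return pd.DataFrame(
            {
                grouping: [True] * len(x) + [False] * len(y),
                "shared_pollinator": True,
                "co_flowered": [True] * len(x) + [False] * len(y),
                "pianka": list(x) + list(y),
            }
        )

    def test_identical_groups_not_significant(self):
        res = wilcoxon_group_test(self.pairs_frame([0.1, 0.5, 0.9], [0.1, 0.5, 0.9]), "co_flowered")
        assert res.p >= 0.5

    def test_exact_p_matches_enumeration(self):
        res = wilcoxon_group_test(self.pairs_frame([0.1, 0.2], [0.8, 0.9]), "co_flowered")
        assert res.W == 0  # no (x, y) pair with x > y
        assert res.p == pytest.approx(rank_sum_oracle([0.1, 0.2], [0.8, 0.9]))
        assert res.p == pytest.approx(1 / 6)

    @pytest.mark.parametrize("seed", range(5))
    def test_small_sample_agreement_with_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nx = int(rng.integers(2, 5))
        ny = int(rng.integers(2, 9 - nx))
        x = rng.random(nx).round(3)
        y = rng.random(ny).round(3)
        res = wilcoxon_group_test(self.pairs_frame(x, y), "co_flowered")
        assert res.p == pytest.approx(rank_sum_oracle(x, y), abs=1e-9)

    def test_shift_invariance(self):
        a = wilcoxon_group_test(self.pairs_frame([0.1, 0.4], [0.2, 0.8]), "co_flowered")
        b = wilcoxon_group_test(
            self.pairs_frame([0.1 + 5, 0.4 + 5], [0.2 + 5, 0.8 + 5]), "co_flowered"
        )
        assert (a.W, a.p) == (b.W, b.p)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            wilcoxon_group_test(self.pairs_frame([0.1], []), "co_flowered")
        with pytest.raises(ValueError, match="grouping"):
            wilcoxon_group_test(self.pairs_frame([0.1], [0.2]), "shared_hummingbird")


def dist_frame(arr, labels):
    return pd.DataFrame(arr, index=labels, columns=labels)


class TestMantel:
    def setup_method(self):
        rng = np.random.default_rng(31)
        pts = rng.random((4, 2))
        from scipy.spatial.distance import pdist, squareform

        self.labels = list("abcd")
        self.d1 = dist_frame(squareform(pdist(pts)), self.labels)
        self.d2 = dist_frame(squareform(pdist(pts + rng.normal(0, 0.3, pts.shape))), self.labels)

    def test_identical_matrices_r_one(self):
        res = mantel_test(self.d1, self.d1.copy(), n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_p_matches_exhaustive_enumeration(self):
        a1, a2 = self.d1.to_numpy(), self.d2.to_numpy()
        iu = np.triu_indices(4, 1)
        r_obs = np.corrcoef(a1[iu], a2[iu])[0, 1]
        count = 0
        perms = list(permutations(range(4)))
        for perm in perms:
            r = np.corrcoef(a1[iu], a2[np.ix_(perm, perm)][iu])[0, 1]
            if r >= r_obs - 1e-12:
                count += 1
        exact = count / len(perms)
        res = mantel_test(self.d1, self.d2, n_perm=20_000, seed=1)
        assert res.r == pytest.approx(r_obs)
        assert res.p == pytest.approx(exact, abs=0.02)

    def test_agrees_with_skbio_r(self):
        skbio_mantel = pytest.importorskip("skbio.stats.distance").mantel
        from skbio import DistanceMatrix

        r, p, n = skbio_mantel(
            DistanceMatrix(self.d1.to_numpy(), self.labels),
            DistanceMatrix(self.d2.to_numpy(), self.labels),
            permutations=999,
            alternative="greater",
        )
        res = mantel_test(self.d1, self.d2, n_perm=999, seed=2)
        assert res.r == pytest.approx(r, abs=1e-12)

    def test_constant_matrix_flagged_degenerate(self):
        flat = dist_frame(np.ones((4, 4)) - np.eye(4), self.labels)
        with pytest.warns(UserWarning, match="zero variance"):
            res = mantel_test(self.d1, flat, n_perm=10, seed=0)
        assert res.degenerate and np.isnan(res.r)

    def test_offset_invariance_of_r(self):
        shifted = self.d2 + 2.0
        shifted.values[np.diag_indices(4)] = 0.0
        a = mantel_test(self.d1, self.d2, n_perm=50, seed=3)
        b = mantel_test(self.d1, shifted, n_perm=50, seed=3)
        assert a.r == pytest.approx(b.r, abs=1e-12)

    def test_asymmetric_matrix_rejected(self):
        bad = self.d2.copy()
        bad.iloc[0, 1] += 1.0
        with pytest.raises(ValueError, match="symmetric"):
            mantel_test(self.d1, bad)


class TestDistances:
    def test_identical_heights_zero_matrix(self):
        prod = pd.DataFrame(np.ones((3, 12)), index=list("abc"))
        d1, _ = build_distance_matrices({"a": 2.0, "b": 2.0, "c": 2.0}, prod)
        assert (d1.to_numpy() == 0).all()

    def test_published_extremes_distance(self):
        # the shortest and tallest anthers in the floral table: 0.67 vs 7.67 cm
        prod = pd.DataFrame(np.ones((2, 12)), index=["short", "tall"])
        d1, _ = build_distance_matrices({"short": 0.67, "tall": 7.67}, prod)
        assert d1.loc["short", "tall"] == pytest.approx(7.00)

    def test_duplicated_plant_twins_have_zero_distance(self):
        prod = pd.DataFrame([[1, 2, 3], [1, 2, 3], [4, 4, 4]], index=["t1", "t2", "u"], dtype=float)
        d1, d2 = build_distance_matrices({"t1": 3.0, "t2": 3.0, "u": 5.0}, prod)
        assert d1.loc["t1", "t2"] == 0 and d2.loc["t1", "t2"] == 0

    def test_missing_plant_rejected(self):
        prod = pd.DataFrame(np.ones((2, 3)), index=["a", "b"])
        with pytest.raises(ValueError, match="c"):
            build_distance_matrices({"a": 1.0, "b": 2.0, "c": 3.0}, prod)
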
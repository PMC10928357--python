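"""Bray–Curtis, ANOSIM and the rank test, cross-checked against scipy/scikit-bio."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from scipy.spatial.distance import braycurtis as scipy_bray

from terrsub.stats import (
    DissimilarityMatrix,
    anosim,
    bray_curtis,
    bray_curtis_matrix,
    rank_sum_test,
)

abund = st.lists(st.floats(0, 100), min_size=2, max_size=8)


class TestBrayCurtis:
    def test_identity(self):
        assert bray_curtis([2, 1, 0], [2, 1, 0]) == 0.0

    def test_disjoint_support_is_one(self):
        assert bray_curtis([5, 0, 3], [0, 2, 0]) == 1.0

    def test_hand_computation(self):
        assert bray_curtis([2, 1], [1, 3]) == pytest.approx(3 / 7)

    def test_all_zero_pair_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis([0, 0], [0, 0])

    @settings(max_examples=100, derandomize=True)
    @given(x=abund, y=abund)
    def test_matches_scipy_and_is_bounded_symmetric(self, x, y):
        n = min(len(x), len(y))
        x, y = np.array(x[:n]), np.array(y[:n])
        if (x + y).sum() == 0:
            return
        d = bray_curtis(x, y)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(bray_curtis(y, x))
        assert d == pytest.approx(scipy_bray(x, y), abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(x=abund, y=abund, c=st.floats(0.01, 100))
    def test_scale_invariance(self, x, y, c):
        n = min(len(x), len(y))
        x, y = np.array(x[:n]), np.array(y[:n])
        if (x + y).sum() == 0:
            return
        assert bray_curtis(c * x, c * y) == pytest.approx(bray_curtis(x, y))


def _separated_matrix(n_per=3, gap=0.5):
    """Block matrix: within-group dissimilarities < all between-group ones."""
    n = 2 * n_per
    rng = np.random.default_rng(0)
    v = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        same = (i < n_per) == (j < n_per)
        v[i, j] = v[j, i] = rng.uniform(0, 0.3) if same else gap + rng.uniform(0, 0.3)
    labels = tuple(f"s{i}" for i in range(n))
    return DissimilarityMatrix(labels, v), ["a"] * n_per + ["b"] * n_per


class TestAnosim:
    def test_complete_separation_gives_r_one(self):
        dm, groups = _separated_matrix()
        res = anosim(dm, groups, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.method == "anosim-exact"  # C(6,3)=20 arrangements enumerated
        assert res.p_value == pytest.approx(1 / 10)  # 2 of 20 labelings reach R=1

    def test_r_matches_scikit_bio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(5)
        x = rng.random((8, 8))
        v = np.triu(x, 1) + np.triu(x, 1).T
        labels = tuple(f"s{i}" for i in range(8))
        dm = DissimilarityMatrix(labels, v)
        groups = ["a"] * 4 + ["b"] * 4
        ours = anosim(dm, groups, seed=1)
        ref = skbio_stats.anosim(
            skbio_stats.DistanceMatrix(v, labels), grouping=groups, permutations=999
        )
        assert ours.statistic == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_mean_permuted_r_near_zero_under_null(self):
        """Label permutations are centred: E[R] = 0 when labels are irrelevant."""
        dm, _ = _separated_matrix(n_per=4)
        groups = np.array(["a"] * 4 + ["b"] * 4)
        rs = []
        for perm in itertools.combinations(range(8), 4):
            lab = np.full(8, "b")
            lab[list(perm)] = "a"
            rs.append(anosim_r_of(dm, lab))
        assert np.mean(rs) == pytest.approx(0.0, abs=1e-12)

    def test_p_respects_permutation_floor(self):
        dm, groups = _separated_matrix(n_per=5)  # C(10,5)=252 enumerated
        res = anosim(dm, groups, seed=2)
        assert res.p_value >= 1 / res.n_permutations

    def test_monte_carlo_branch_used_for_large_designs(self):
        rng = np.random.default_rng(8)
        n = 22  # C(22,11) >> enumeration limit
        x = rng.random((n, n))
        v = np.triu(x, 1) + np.triu(x, 1).T
        dm = DissimilarityMatrix(tuple(f"s{i}" for i in range(n)), v)
        res = anosim(dm, ["a"] * 11 + ["b"] * 11, n_permutations=99, seed=3)
        assert res.method == "anosim"
        assert res.p_value >= 1 / 100

    def test_small_group_rejected(self):
        dm, _ = _separated_matrix()
        with pytest.raises(ValueError, match="2 members"):
            anosim(dm, ["a"] + ["b"] * 5, seed=0)

    def test_three_group_enumeration(self):
        """Multiset enumeration covers >2 groups as well."""
        rng = np.random.default_rng(11)
        x = rng.random((6, 6))
        v = np.triu(x, 1) + np.triu(x, 1).T
        dm = DissimilarityMatrix(tuple(f"s{i}" for i in range(6)), v)
        res = anosim(dm, ["a", "a", "b", "b", "c", "c"], seed=0)
        assert res.method == "anosim-exact"
        assert res.n_permutations == 90  # 6!/(2!2!2!)


def anosim_r_of(dm: DissimilarityMatrix, labels) -> float:
    """Observed R only (helper mirroring the implementation's definition)."""
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ranks = sps.rankdata(dm.values[iu])
    within = np.asarray(labels)[iu[0]] == np.asarray(labels)[iu[1]]
    m = n * (n - 1) // 2
    return (ranks[~within].mean() - ranks[within].mean()) / (m / 2)


class TestRankSumTest:
    def test_separated_three_vs_three(self):
        res = rank_sum_test([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert res.statistic == pytest.approx(3.857, abs=0.001)
        assert res.p_value == pytest.approx(0.0495, abs=0.0001)

    def test_exact_three_vs_three(self):
        res = rank_sum_test([1.0, 2.0, 3.0], [10.0, 11.0, 12.0], mode="exact")
        assert res.p_value == pytest.approx(2 / 20)

    def test_identical_samples_give_zero(self):
        res = rank_sum_test([1.0, 2.0], [2.0, 1.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    @settings(max_examples=60, derandomize=True)
    @given(
        a=st.lists(st.integers(0, 9), min_size=2, max_size=10).map(
            lambda v: [float(x) for x in v]
        ),
        b=st.lists(st.integers(0, 9), min_size=2, max_size=10).map(
            lambda v: [float(x) for x in v]
        ),
    )
    def test_chi_square_mode_matches_kruskal_and_z_squared(self, a, b):
        res = rank_sum_test(a, b)
        if len(set(a) | set(b)) > 1:
            ref = sps.kruskal(a, b)
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-9)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)
        z = rank_sum_test(a, b, mode="z")
        assert res.statistic == pytest.approx(z.statistic**2, abs=1e-9)

    @settings(max_examples=40, derandomize=True)
    @given(
        a=st.lists(st.floats(0, 100), min_size=2, max_size=6),
        b=st.lists(st.floats(0, 100), min_size=2, max_size=6),
    )
    def test_exact_mode_matches_scipy_enumeration(self, a, b):
        if len(set(a) | set(b)) < len(a) + len(b):
            return  # scipy's exact method does not handle ties
        res = rank_sum_test(a, b, mode="exact")
        ref = sps.mannwhitneyu(a, b, method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_z_mode_matches_scipy_without_continuity(self):
        a = [3.0, 1.0, 4.0, 1.5]
        b = [9.0, 2.6, 5.0, 3.5, 8.0]
        res = rank_sum_test(a, b, mode="z")
        ref = sps.mannwhitneyu(a, b, method="asymptotic", use_continuity=False)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_mode_size_limit(self):
        with pytest.raises(ValueError, match="n <= 12"):
            rank_sum_test(list(range(7)), list(range(7)), mode="exact")

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            rank_sum_test([], [1.0])


class TestDissimilarityMatrix:
    def test_asymmetric_rejected(self):
        v = np.array([[0, 0.2], [0.3, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            DissimilarityMatrix(("a", "b"), v)

    def test_bray_curtis_matrix_shape_and_values(self):
        m = pd.DataFrame({"x": [2, 1], "y": [1, 3]}, index=["s1", "s2"])
        dm = bray_curtis_matrix(m)
        assert dm.values[0, 1] == pytest.approx(3 / 7)
        assert dm.labels == ("s1", "s2")
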
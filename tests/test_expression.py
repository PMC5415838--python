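"""Normalisation, fold changes, the two-library exact test, clustering."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy.stats import nbinom

from mirstage.expression import (
    CountPair,
    ac_probability,
    ac_pvalue,
    classify_de,
    cluster_prep,
    de_table,
    log2_fold_change,
    normalize,
    top_n,
)

N_P, N_D1, N_D3 = 5_871_055, 5_922_188, 5_935_963


class TestNormalize:
    def test_full_library_is_one_million(self):
        assert normalize(100, 100) == 1e6

    def test_zero_count_floors_at_001(self):
        assert normalize(0, N_P) == 0.01

    def test_arithmetic(self):
        assert normalize(7, N_D3) == pytest.approx(1.1793, abs=1e-4)

    def test_bad_total(self):
        with pytest.raises(ValueError):
            normalize(1, 0)


class TestFoldChange:
    @pytest.mark.parametrize(
        "x,y,n1,n2,expected",
        [
            (16887, 38687, N_P, N_D1, 1.18),
            (27, 990, N_P, N_D3, 5.18),
            (0, 7, N_P, N_D3, 6.88),  # floored denominator
            (51, 121, N_P, N_D1, 1.23),
        ],
    )
    def test_published_style_pairs(self, x, y, n1, n2, expected):
        fc = log2_fold_change(CountPair(x, y, n1, n2))
        assert fc == pytest.approx(expected, abs=0.01)

    def test_identity(self):
        assert log2_fold_change(CountPair(5, 5, 1000, 1000)) == 0.0

    def test_antisymmetry_under_swap(self):
        pair = CountPair(12, 77, 10**6, 2 * 10**6)
        assert log2_fold_change(pair) == pytest.approx(
            -log2_fold_change(pair.swapped())
        )


def _exact_mass(x, y, N1, N2):
    r = Fraction(N2, N1)
    return (
        r**y
        * Fraction(math.factorial(x + y), math.factorial(x) * math.factorial(y))
        / (1 + r) ** (x + y + 1)
    )


class TestMass:
    def test_x0_y0_equal_totals_is_half(self):
        assert ac_probability(CountPair(0, 0, 10**6, 10**6)) == pytest.approx(0.5)

    @pytest.mark.parametrize("x,y", [(5, 9), (0, 3), (40, 12), (1000, 950)])
    def test_agrees_with_exact_rational_oracle(self, x, y):
        pair = CountPair(x, y, 10**6, 3 * 10**6)
        exact = float(_exact_mass(x, y, 10**6, 3 * 10**6))
        assert ac_probability(pair) == pytest.approx(exact, rel=1e-12)

    def test_is_negative_binomial_mass(self):
        # independent cross-check: the mass equals NB(y; x+1, N1/(N1+N2))
        x, y, N1, N2 = 17, 40, 10**6, 2 * 10**6
        assert ac_probability(CountPair(x, y, N1, N2)) == pytest.approx(
            nbinom.pmf(y, x + 1, N1 / (N1 + N2)), rel=1e-10
        )

    def test_normalisation_sums_to_one(self):
        for x in (0, 7, 20):
            total = sum(
                ac_probability(CountPair(x, 0, 10**6, 10**6), y=k)
                for k in range(0, 400)
            )
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_finite_at_large_counts(self):
        p = ac_probability(CountPair(10**7, 10**7, 10**7, 10**7))
        assert 0 <= p < 1 and np.isfinite(p)


class TestPvalue:
    def test_equal_counts_equal_totals_is_one(self):
        assert ac_pvalue(CountPair(9, 9, 10**6, 10**6)) == pytest.approx(1.0, abs=1e-9)

    def test_extreme_imbalance_is_tiny(self):
        assert ac_pvalue(CountPair(50, 0, 10**6, 10**6)) < 1e-10

    def test_matches_nbinom_tail_oracle(self):
        x, y, N1, N2 = 30, 55, 10**6, 10**6
        q = N1 / (N1 + N2)
        C = nbinom.cdf(y, x + 1, q)
        expected = 2 * min(C, 1 - C)
        assert ac_pvalue(CountPair(x, y, N1, N2)) == pytest.approx(expected, rel=1e-9)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            x, y = (int(v) for v in rng.integers(0, 500, 2))
            n1, n2 = (int(v) for v in rng.integers(10**5, 10**7, 2))
            pair = CountPair(x, y, n1, n2)
            assert ac_pvalue(pair) == pytest.approx(
                ac_pvalue(pair.swapped()), rel=1e-9
            )

    def test_in_unit_interval(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            x, y = (int(v) for v in rng.integers(0, 2000, 2))
            p = ac_pvalue(CountPair(x, y, 10**6, 10**6))
            assert 0 < p <= 1


class TestClassify:
    def test_ratio_over_two_is_up(self):
        assert classify_de(1.0, 2.97) == "up"

    def test_ratio_one_is_equal(self):
        assert classify_de(5.0, 5.0) == "equal"

    def test_ratio_point4_is_down(self):
        assert classify_de(1.0, 0.4) == "down"

    def test_half_boundary_is_down(self):
        assert classify_de(2.0, 1.0) == "down"


def test_de_table_round_trip():
    counts = pd.DataFrame(
        {"a": [100, 7, 0], "b": [400, 7, 50]},
        index=pd.Index(["m1", "m2", "m3"], name="miRNA"),
    )
    df = de_table(counts, {"a": 10**6, "b": 10**6}, "a", "b")
    assert df.at["m1", "de_class"] == "up"
    assert df.at["m2", "de_class"] == "equal"
    assert df.at["m3", "de_class"] == "up"
    assert (df["p_value"] > 0).all() and (df["p_value"] <= 1).all()


class TestClusterPrep:
    def test_constant_row_centres_to_zero(self):
        ne = pd.DataFrame({"a": [5.0, 1.0], "b": [5.0, 8.0], "c": [5.0, 64.0]},
                          index=["flat", "var"])
        t, _ = cluster_prep(ne)
        assert (t.loc["flat"] == 0).all()

    def test_identical_rows_merge_at_zero_distance(self):
        ne = pd.DataFrame(
            {"a": [1.0, 1.0, 8.0], "b": [4.0, 4.0, 2.0], "c": [16.0, 16.0, 1.0]},
            index=["r1", "r2", "r3"],
        )
        _, tree = cluster_prep(ne)
        # first merge joins the two identical rows at distance 0
        assert tree[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(tree[0, 0]), int(tree[0, 1])} == {0, 1}

    def test_two_block_structure_recovered(self):
        rng = np.random.default_rng(4)
        up = np.outer(np.ones(4), [1.0, 8.0, 64.0]) * rng.uniform(0.5, 2, (4, 1))
        down = np.outer(np.ones(4), [64.0, 8.0, 1.0]) * rng.uniform(0.5, 2, (4, 1))
        ne = pd.DataFrame(
            np.vstack([up, down]), columns=["a", "b", "c"],
            index=[f"m{i}" for i in range(8)],
        )
        _, tree = cluster_prep(ne)
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(tree, t=2, criterion="maxclust")
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]


class TestTopN:
    def test_planted_top_is_recovered(self, small_dataset):
        exp = small_dataset.truth.expected_counts
        ne = exp / exp.sum() * 1e6
        best = top_n(ne, "stage0", 1)
        assert best.index[0] == exp["stage0"].idxmax()

    def test_n_larger_than_table(self):
        ne = pd.DataFrame({"a": [3.0, 1.0]}, index=["x", "y"])
        assert len(top_n(ne, "a", 10)) == 2

    def test_stable_under_row_permutation(self):
        ne = pd.DataFrame({"a": [3.0, 1.0, 2.0]}, index=["x", "y", "z"])
        perm = ne.loc[["z", "x", "y"]]
        assert list(top_n(ne, "a", 3).index) == list(top_n(perm, "a", 3).index)
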
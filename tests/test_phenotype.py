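import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from teadiv import phenotype as ph
from teadiv.core import DistanceMatrix, PhenotypeTable
from teadiv.trees import cut_tree


class TestCategoryFrequencies:
    def test_tree_type_distribution(self):
        codes = [2] * 35 + [3] * 5
        f = ph.category_frequencies(codes)
        assert f.codes == (2, 3)
        assert f.proportions == (0.875, 0.125)

    def test_all_identical(self):
        f = ph.category_frequencies([4, 4, 4])
        assert f.proportions == (1.0,)

    def test_uniform_four(self):
        f = ph.category_frequencies([1, 2, 3, 4])
        assert f.proportions == (0.25,) * 4

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ph.category_frequencies([])


class TestShannonIndex:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ((0.875, 0.125), 0.3768),
            ((1.0,), 0.0),
            ((0.25, 0.50, 0.25), 1.0397),
            ((0.25,) * 4, math.log(4)),
        ],
    )
    def test_known_values(self, p, expected):
        assert ph.shannon_index(np.array(p)) == pytest.approx(expected, abs=1e-4)

    @given(st.lists(st.floats(0.01, 10), min_size=2, max_size=8))
    @settings(deadline=None)
    def test_bounded_by_uniform(self, weights):
        p = np.array(weights) / sum(weights)
        h = ph.shannon_index(p)
        assert -1e-12 <= h <= math.log(len(p)) + 1e-12

    def test_maximal_for_uniform(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = rng.integers(2, 7)
            p = rng.dirichlet(np.ones(k))
            assert ph.shannon_index(p) <= math.log(k) + 1e-12
        assert ph.shannon_index(np.full(5, 0.2)) == pytest.approx(math.log(5))


class TestCoefficientOfVariation:
    def test_tree_type_codes(self):
        assert ph.coefficient_of_variation([2] * 35 + [3] * 5) == pytest.approx(
            15.76, abs=0.005
        )

    def test_leaf_base_codes(self):
        assert ph.coefficient_of_variation([1] * 35 + [2] * 5) == pytest.approx(
            29.77, abs=0.005
        )

    def test_constant_vector(self):
        assert ph.coefficient_of_variation([3.0, 3.0, 3.0]) == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.random(30) + 0.5
        assert ph.coefficient_of_variation(7.3 * x) == pytest.approx(
            ph.coefficient_of_variation(x)
        )

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            ph.coefficient_of_variation([-1.0, 1.0])


class TestGrading:
    def test_all_equal_single_class(self):
        with pytest.warns(UserWarning, match="zero SD"):
            codes = ph.grade_quantitative([5.0] * 10)
        f = ph.category_frequencies(codes)
        assert ph.shannon_index(f) == 0.0

    def test_normal_sample_matches_bin_masses(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=10_000)
        codes = ph.grade_quantitative(x, n_classes=10)
        edges = np.concatenate([[-np.inf], -2 + 0.5 * np.arange(9), [np.inf]])
        expected = np.diff(norm.cdf(edges))
        observed = np.bincount(codes, minlength=11)[1:] / x.size
        assert np.all(np.abs(observed - expected) < 0.02)

    def test_extremes_in_end_classes(self):
        x = np.concatenate([np.zeros(50), [100.0], [-100.0]])
        codes = ph.grade_quantitative(x)
        assert codes[-2] == 10 and codes[-1] == 1


class TestStandardize:
    def test_zscores(self):
        df = pd.DataFrame({"t": [1.0, 2.0, 3.0]})
        z = ph.standardize(df)
        assert np.allclose(z["t"], [-1, 0, 1])
        assert abs(z["t"].mean()) < 1e-9
        assert z["t"].std(ddof=1) == pytest.approx(1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.random((12, 4)), columns=list("abcd"))
        z = ph.standardize(df)
        assert np.allclose(ph.standardize(z).to_numpy(), z.to_numpy(), atol=1e-9)

    def test_zero_sd_trait_dropped(self):
        df = pd.DataFrame({"flat": [1.0, 1.0, 1.0], "ok": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning, match="zero SD"):
            z = ph.standardize(df)
        assert list(z.columns) == ["ok"]


class TestEuclidean:
    def test_identical_rows_zero(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        assert ph.euclidean_matrix(df).get("a", "b") == 0.0

    def test_three_four_five(self):
        df = pd.DataFrame([[0.0, 0.0], [3.0, 4.0]], index=["a", "b"])
        assert ph.euclidean_matrix(df).get("a", "b") == pytest.approx(5.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.random((10, 5)), index=[f"s{i}" for i in range(10)])
        d = ph.euclidean_matrix(df)
        for i in range(10):
            for j in range(10):
                expected = math.sqrt(((df.iloc[i] - df.iloc[j]) ** 2).sum())
                assert d.values[i, j] == pytest.approx(expected)

    def test_missing_rejected(self):
        df = pd.DataFrame([[1.0, np.nan], [0.0, 0.0]], index=["a", "b"])
        with pytest.raises(ValueError, match="imput"):
            ph.euclidean_matrix(df)


class TestClustering:
    def test_three_leaf_manual_average_linkage(self):
        # d(a,b)=2, d(a,c)=8, d(b,c)=6 -> merge (a,b) at 1, then c at (8+6)/2/2
        d = DistanceMatrix.from_lower_triangle(
            ["a", "b", "c"], {("a", "b"): 2.0, ("a", "c"): 8.0, ("b", "c"): 6.0}
        )
        tree = ph.hierarchical_cluster(d)
        assert tree.merges[0].height == pytest.approx(1.0)
        assert set(tree.merges[0].left + tree.merges[0].right) == {"a", "b"}
        assert tree.merges[1].height == pytest.approx(3.5)

    def test_recovers_planted_phenotype_clusters(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(5)
        centers = rng.normal(scale=6.0, size=(3, 6))
        rows, truth = [], []
        for c in range(3):
            rows.append(centers[c] + rng.normal(size=(12, 6)))
            truth += [c] * 12
        df = pd.DataFrame(np.vstack(rows), index=[f"s{i}" for i in range(36)])
        tree = ph.hierarchical_cluster(ph.euclidean_matrix(ph.standardize(df)))
        groups = cut_tree(tree, k=3)
        labels = [groups[f"s{i}"] for i in range(36)]
        assert adjusted_rand_score(truth, labels) >= 0.9


class TestCutTree:
    def test_cut_at_zero_gives_singletons(self):
        d = DistanceMatrix.from_lower_triangle(
            ["a", "b", "c"], {("a", "b"): 2.0, ("a", "c"): 8.0, ("b", "c"): 6.0}
        )
        tree = ph.hierarchical_cluster(d)
        assert len(set(cut_tree(tree, height=0.0).values())) == 3

    def test_cut_above_root_single_group(self):
        d = DistanceMatrix.from_lower_triangle(
            ["a", "b", "c"], {("a", "b"): 2.0, ("a", "c"): 8.0, ("b", "c"): 6.0}
        )
        tree = ph.hierarchical_cluster(d)
        assert set(cut_tree(tree, height=100.0).values()) == {0}

    def test_both_arguments_rejected(self):
        d = DistanceMatrix.from_lower_triangle(["a", "b"], {("a", "b"): 1.0})
        tree = ph.hierarchical_cluster(d)
        with pytest.raises(ValueError):
            cut_tree(tree, height=1.0, k=2)


def test_summarize_descriptive_matches_componentwise():
    rng = np.random.default_rng(11)
    df = pd.DataFrame(
        {"t1": rng.integers(1, 4, 40), "t2": rng.integers(1, 3, 40)},
        index=[f"s{i}" for i in range(40)],
    )
    for s in ph.summarize_descriptive(df):
        codes = df[s.trait]
        assert s.cv == pytest.approx(ph.coefficient_of_variation(codes))
        assert s.shannon == pytest.approx(
            ph.shannon_index(ph.category_frequencies(codes))
        )
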
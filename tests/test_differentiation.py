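import itertools
import math

import numpy as np
import pytest

from teadiv import differentiation as diff
from teadiv.core import DistanceMatrix, GenotypeMatrix, PopulationMap
from teadiv.datasets import load_fst_nm
from teadiv.markers import allele_frequencies
from teadiv.simulate import SimulationConfig, simulate_allele_freqs, simulate_genotypes

from conftest import random_distance_matrix


def _brute_force_total_ss(g: GenotypeMatrix) -> float:
    """Total SS from the grand allele-copy mismatch matrix: (1/2N) sum_{i<j} d."""
    copies = np.transpose(g.calls, (0, 2, 1)).reshape(2 * g.n_individuals, g.n_loci)
    total = 0.0
    for i, j in itertools.combinations(range(copies.shape[0]), 2):
        total += np.sum(copies[i] != copies[j])
    return total / copies.shape[0]


class TestAmova:
    def test_degrees_of_freedom_for_survey_design(self, study_bundle):
        res = diff.amova(study_bundle.genotypes, study_bundle.popmap)
        assert list(res.table["df"].iloc[:3]) == [6, 33, 40]
        assert res.table["df"].iloc[:3].sum() == 79  # 2N - 1

    def test_fully_fixed_divergent_populations(self):
        calls = np.empty((8, 5, 2), dtype=int)
        calls[:4] = 100
        calls[4:] = 200
        g = GenotypeMatrix([f"i{k}" for k in range(8)], [f"L{j}" for j in range(5)], calls)
        m = PopulationMap({f"i{k}": ("A" if k < 4 else "B") for k in range(8)})
        res = diff.amova(g, m)
        assert res.fst == pytest.approx(1.0)
        assert res.table["percent"].iloc[0] == pytest.approx(100.0)

    def test_panmictic_split_has_no_among_component(self):
        cfg = SimulationConfig(pop_sizes=(100, 100), n_clusters=1,
                               pop_clusters=(0, 0), n_loci=10, seed=9)
        rng = np.random.default_rng(9)
        freqs = simulate_allele_freqs(cfg, rng)
        g, m, _ = simulate_genotypes(freqs, cfg, rng)
        res = diff.amova(g, m)
        assert abs(res.components_raw[0]) <= 0.05 * res.table.loc["Total", "sigma2"] + 1e-9

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_ss_decomposition_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        calls = rng.integers(1, 4, size=(n, 3, 2))
        g = GenotypeMatrix([f"i{k}" for k in range(n)], [f"L{j}" for j in range(3)], calls)
        m = PopulationMap(
            {f"i{k}": ("A" if k < 5 else "B" if k < 9 else "C") for k in range(n)}
        )
        res = diff.amova(g, m)
        assert res.table.loc["Total", "SS"] == pytest.approx(_brute_force_total_ss(g))
        ms = res.table["MS"].iloc[:3]
        assert np.allclose(ms, res.table["SS"].iloc[:3] / res.table["df"].iloc[:3])

    def test_fst_equals_among_percent(self, study_bundle):
        res = diff.amova(study_bundle.genotypes, study_bundle.popmap)
        assert res.fst == pytest.approx(res.table["percent"].iloc[0] / 100.0)

    def test_singleton_population_rejected(self):
        g = GenotypeMatrix(["a", "b", "c"], ["L1"], np.full((3, 1, 2), 100))
        m = PopulationMap({"a": "A", "b": "A", "c": "B"})
        with pytest.raises(ValueError, match="'B'"):
            diff.amova(g, m)


class TestPairwiseFst:
    def test_identical_frequencies_near_zero(self):
        cfg = SimulationConfig(pop_sizes=(200, 200), n_clusters=1,
                               pop_clusters=(0, 0), n_loci=12, seed=3)
        rng = np.random.default_rng(3)
        freqs = simulate_allele_freqs(cfg, rng)
        g, m, _ = simulate_genotypes(freqs, cfg, rng)
        assert diff.pairwise_fst(g, m).fst.values[0, 1] < 0.02

    def test_fixed_divergent_pair_is_one(self):
        calls = np.empty((8, 5, 2), dtype=int)
        calls[:4] = 100
        calls[4:] = 200
        g = GenotypeMatrix([f"i{k}" for k in range(8)], [f"L{j}" for j in range(5)], calls)
        m = PopulationMap({f"i{k}": ("A" if k < 4 else "B") for k in range(8)})
        dm = diff.pairwise_fst(g, m)
        assert dm.fst.get("A", "B") == pytest.approx(1.0)
        assert dm.nm.loc["A", "B"] == 0.0

    def test_recovers_simulated_truth(self):
        # truth = large-sample estimate under the same drawn frequencies
        cfg = SimulationConfig(pop_sizes=(50, 50), n_clusters=2, pop_clusters=(0, 1),
                               n_loci=14, allele_range=(4, 15), fst_target=0.2, seed=0)
        rng = np.random.default_rng(0)
        freqs = simulate_allele_freqs(cfg, rng)
        g, m, _ = simulate_genotypes(freqs, cfg, rng)
        est = diff.pairwise_fst(g, m).fst.values[0, 1]
        big = SimulationConfig(pop_sizes=(1500, 1500), n_clusters=2,
                               pop_clusters=(0, 1), n_loci=14, fst_target=0.2)
        gb, mb, _ = simulate_genotypes(freqs, big, np.random.default_rng(99))
        truth = diff.pairwise_fst(gb, mb).fst.values[0, 1]
        assert abs(est - truth) <= 0.05


class TestGeneFlow:
    @pytest.mark.parametrize(
        "fst, expected", [(0.38, 0.4079), (0.25, 0.75), (0.5, 0.25)]
    )
    def test_island_model_values(self, fst, expected):
        assert diff.gene_flow(fst) == pytest.approx(expected, abs=1e-4)

    def test_boundaries(self):
        with pytest.warns(UserWarning, match="unbounded"):
            assert diff.gene_flow(0.0) == math.inf
        assert diff.gene_flow(1.0) == 0.0

    def test_printed_matrix_internal_consistency(self):
        # (1-Fst)/(4 Fst) reproduces the printed Nm within the rounding of
        # Fst: the printed Nm must sit within 0.15 of the Nm interval induced
        # by the 2-dp rounding interval of the printed Fst
        fst, nm = load_fst_nm()
        for a, b in itertools.combinations(fst.index, 2):
            f = fst.loc[a, b]
            lo, hi = diff.gene_flow(f + 0.005), diff.gene_flow(f - 0.005)
            residual = max(0.0, lo - nm.loc[a, b], nm.loc[a, b] - hi)
            assert residual <= 0.15, (a, b)


class TestNeiDistance:
    def test_identical_tables_zero(self, study_bundle):
        f = allele_frequencies(study_bundle.genotypes)
        d = diff.nei_distance({"X": f, "Y": f})
        assert d.get("X", "Y") == 0.0

    def test_hand_computed_single_locus(self):
        from teadiv.markers import AlleleFreqTable

        fx = AlleleFreqTable({"L": {1: 0.8, 2: 0.2}}, {"L": 20})
        fy = AlleleFreqTable({"L": {1: 0.2, 2: 0.8}}, {"L": 20})
        d = diff.nei_distance({"X": fx, "Y": fy})
        assert d.get("X", "Y") == pytest.approx(-math.log(0.32 / 0.68), abs=1e-4)

    def test_symmetric_zero_diagonal_on_random(self, study_bundle):
        g, m = study_bundle.genotypes, study_bundle.popmap
        freqs = {p: allele_frequencies(g, m.individuals_in(p)) for p in m.populations}
        d = diff.nei_distance(freqs)
        assert np.allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)
        assert np.all(d.values >= 0)


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        d = random_distance_matrix(list("ABCDE"), rng)
        r, p = diff.mantel_test(d, d, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        d1 = random_distance_matrix(list("ABCDE"), rng)
        v = 3.0 * d1.values + 2.0
        np.fill_diagonal(v, 0.0)
        d2 = DistanceMatrix(d1.labels, v)
        r, _ = diff.mantel_test(d1, d2, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_matches_exhaustive_permutations(self):
        rng = np.random.default_rng(2)
        d1 = random_distance_matrix(list("ABCD"), rng)
        d2 = random_distance_matrix(list("ABCD"), rng)
        il = np.tril_indices(4, k=-1)
        x = d1.values[il]

        def corr(mat):
            y = mat[il]
            return np.corrcoef(x, y)[0, 1]

        r_obs = corr(d2.values)
        count = sum(
            corr(d2.values[np.ix_(perm, perm)]) >= r_obs - 1e-12
            for perm in itertools.permutations(range(4))
        )
        p_exact = count / 24  # every permutation enumerated once
        r, p_mc = diff.mantel_test(d1, d2, n_perm=20_000, seed=5)
        assert r == pytest.approx(r_obs)
        assert p_mc == pytest.approx(p_exact, abs=0.02)

    def test_agrees_with_skbio(self):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import mantel as sk_mantel

        rng = np.random.default_rng(3)
        d1 = random_distance_matrix(list("ABCDEFG"), rng)
        d2 = random_distance_matrix(list("ABCDEFG"), rng)
        r_ours, p_ours = diff.mantel_test(d1, d2, n_perm=9_999, seed=0)
        r_sk, p_sk, _ = sk_mantel(
            SkDM(d1.values, d1.labels), SkDM(d2.values, d2.labels),
            permutations=9_999, alternative="greater", seed=0,
        )
        assert r_ours == pytest.approx(r_sk, abs=1e-10)
        assert p_ours == pytest.approx(p_sk, abs=0.03)

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        d1 = random_distance_matrix(list("ABC"), rng)
        d2 = random_distance_matrix(list("ABX"), rng)
        with pytest.raises(ValueError, match="labels"):
            diff.mantel_test(d1, d2, n_perm=99)

    def test_label_order_irrelevant(self):
        rng = np.random.default_rng(6)
        d1 = random_distance_matrix(list("ABCDE"), rng)
        d2 = random_distance_matrix(list("ABCDE"), rng)
        perm = [3, 1, 4, 0, 2]
        d2_shuffled = DistanceMatrix(
            [d2.labels[i] for i in perm], d2.values[np.ix_(perm, perm)]
        )
        r1, _ = diff.mantel_test(d1, d2, n_perm=99, seed=0)
        r2, _ = diff.mantel_test(d1, d2_shuffled, n_perm=99, seed=0)
        assert r1 == pytest.approx(r2)
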
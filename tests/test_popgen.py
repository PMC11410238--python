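"""Diversity, differentiation, divergence time, thinning and NJ trees."""

from io import StringIO

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from intertaxon.popgen import (
    VariantTable,
    filter_variants,
    generations_since_divergence,
    hudson_fst,
    nj_tree,
    nucleotide_diversity,
    pairwise_divergence,
    thin_variants,
    watterson_theta,
)
from intertaxon.simulate import SimConfig, evolve_lineage, generate_ancestor

from conftest import genotype_table


class TestThinning:
    def test_greedy_hand_trace(self):
        assert thin_variants([100, 300, 700, 1300], 500) == [100, 700, 1300]

    def test_single_site_kept(self):
        assert thin_variants([42], 500) == [42]

    def test_zero_spacing_keeps_all(self):
        assert thin_variants([1, 2, 3], 0) == [1, 2, 3]

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.integers(min_value=1, max_value=10**6), min_size=0, max_size=50))
    def test_idempotence(self, positions):
        positions = sorted(positions)
        once = thin_variants(positions, 500)
        assert thin_variants(once, 500) == once


class TestDiversity:
    def test_two_haplotypes_one_difference(self):
        table = genotype_table([[0, 1]], {"s0": "p", "s1": "p"}, L=1000)
        assert nucleotide_diversity(table, "p").pi == pytest.approx(0.001, abs=1e-12)

    def test_monomorphic_population_has_zero_pi(self):
        table = genotype_table([[1, 1], [0, 0]], {"s0": "p", "s1": "p"}, L=1000)
        res = nucleotide_diversity(table, "p")
        assert res.pi == 0.0
        assert res.S == 0

    def test_matches_brute_force_pairwise_oracle(self):
        g = np.array([[0, 1, 1, 0], [1, 1, 0, 0], [0, 0, 0, 1]])
        L = 500
        table = genotype_table(g, {f"s{i}": "p" for i in range(4)}, L=L)
        pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        oracle = np.mean([np.sum(g[:, i] != g[:, j]) for i, j in pairs]) / L
        assert nucleotide_diversity(table, "p").pi == pytest.approx(oracle, abs=1e-9)

    def test_single_sample_rejected(self):
        table = genotype_table([[1]], {"s0": "p"}, L=100)
        with pytest.raises(ValueError):
            nucleotide_diversity(table, "p")


class TestWatterson:
    def test_no_segregating_sites(self):
        assert watterson_theta(0, 4, 1000) == 0.0

    def test_harmonic_sum_arithmetic(self):
        # a_3 = 1 + 1/2 + 1/3 = 11/6
        assert watterson_theta(5, 4, 1000) == pytest.approx(5 / ((11 / 6) * 1000), abs=1e-12)

    def test_two_samples(self):
        assert watterson_theta(3, 2, 1000) == pytest.approx(0.003, abs=1e-12)

    def test_pi_and_theta_agree_under_neutral_coalescent(self):
        # independent simulator as the oracle for estimator calibration
        import msprime

        pis, thetas = [], []
        for rep in range(50):
            ts = msprime.sim_ancestry(
                samples=10, ploidy=1, population_size=1_000,
                sequence_length=10_000, random_seed=rep + 1,
            )
            ts = msprime.sim_mutations(
                ts, rate=1e-5, random_seed=rep + 1, discrete_genome=False
            )
            g = ts.genotype_matrix()
            g = g[(g.max(axis=1) <= 1)]
            table = genotype_table(g, {f"s{i}": "p" for i in range(10)}, L=10_000)
            res = nucleotide_diversity(table, "p")
            pis.append(res.pi)
            thetas.append(res.theta_w)
        ratio = np.mean(pis) / np.mean(thetas)
        assert 0.9 <= ratio <= 1.1


class TestPairwiseDivergence:
    def test_identical_clone_groups(self):
        g = np.array([[1, 1, 1, 1], [0, 0, 0, 0]])
        table = genotype_table(g, {"s0": "a", "s1": "a", "s2": "b", "s3": "b"}, L=100)
        assert pairwise_divergence(table, ["s0", "s1"], ["s2", "s3"]) == 0.0

    def test_simple_arithmetic(self):
        g = np.zeros((103, 2), dtype=int)
        g[:, 1] = 1
        table = genotype_table(g, {"s0": "a", "s1": "b"}, L=10_000)
        assert pairwise_divergence(table, ["s0"], ["s1"]) == pytest.approx(0.0103, abs=1e-12)

    def test_overlapping_groups_rejected(self):
        table = genotype_table([[0, 1]], {"s0": "a", "s1": "b"}, L=100)
        with pytest.raises(ValueError):
            pairwise_divergence(table, ["s0"], ["s0"])

    def test_recovers_simulation_truth_within_binomial_bounds(self):
        L, d = 100_000, 0.0103
        anc = generate_ancestor(SimConfig(ancestor_length=L, seed=15))
        a, _ = evolve_lineage(anc, d / 2, seed=16)
        b, _ = evolve_lineage(anc, d / 2, seed=17)
        est = pairwise_divergence((a, b))
        expected = 2 * (d / 2) - (4 / 3) * (d / 2) ** 2
        sd = np.sqrt(expected * (1 - expected) / L)
        assert abs(est - expected) <= 3 * sd


class TestHudsonFst:
    def test_fixed_differences_give_exactly_one(self):
        g = np.hstack([np.ones((20, 5), dtype=int), np.zeros((20, 5), dtype=int)])
        table = genotype_table(
            g, {f"s{i}": ("a" if i < 5 else "b") for i in range(10)}, L=100
        )
        assert hudson_fst(table, "a", "b").fst == 1.0

    def test_single_site_hand_formula(self):
        # p_a = 1 (n=10), p_b = 0.5 (n=10):
        # N = 0.25 - 0 - 0.25/9, D = 0.5  ->  Fst = 4/9
        g = np.array([[1] * 10 + [1] * 5 + [0] * 5])
        table = genotype_table(
            g, {f"s{i}": ("a" if i < 10 else "b") for i in range(20)}, L=100
        )
        res = hudson_fst(table, "a", "b")
        assert res.fst == pytest.approx(4 / 9, abs=1e-9)
        assert res.estimator == "Hudson ratio-of-averages"

    def test_panmixia_gives_near_zero(self):
        rng = np.random.default_rng(23)
        freqs = rng.uniform(0.1, 0.9, size=1_000)
        g = (rng.random((1_000, 100)) < freqs[:, None]).astype(int)
        table = genotype_table(
            g, {f"s{i}": ("a" if i < 50 else "b") for i in range(100)}, L=1_000
        )
        assert abs(hudson_fst(table, "a", "b").fst) < 0.02

    def test_small_population_rejected(self):
        table = genotype_table([[1, 0]], {"s0": "a", "s1": "b"}, L=10)
        with pytest.raises(ValueError):
            hudson_fst(table, "a", "b")


class TestFiltering:
    def test_all_pass_is_identity(self):
        table = genotype_table(
            [[0, 1], [1, 0]], {"s0": "a", "s1": "a"}, L=100,
            depth=[[20, 20], [30, 30]], qual=[50.0, 60.0],
        )
        out = filter_variants(table)
        assert out.n_sites == 2

    def test_low_depth_site_removed_strictly(self):
        table = genotype_table(
            [[0, 1], [1, 0], [1, 1]], {"s0": "a", "s1": "a"}, L=100,
            depth=[[9, 50], [10, 50], [11, 50]], qual=[50.0, 50.0, 50.0],
        )
        out = filter_variants(table, min_depth=10)
        assert out.n_sites == 1  # depth must be > 10 in every sample

    def test_quality_and_missing_filters_count(self):
        table = genotype_table(
            [[0, 1], [1, 0], [-1, 1], [1, 1], [0, 0]],
            {"s0": "a", "s1": "a"}, L=100,
            qual=[50.0, 10.0, 50.0, 50.0, 50.0],
        )
        out = filter_variants(table, min_quality=30)
        assert out.n_sites == 3


class TestDivergenceTime:
    def test_zero_divergence(self):
        assert generations_since_divergence(0.0).generations == 0.0

    def test_sister_lineage_divergence_examples(self):
        # d = 1.03% -> 2.80e7 generations; d = 4.06% -> 1.10e8 generations
        res1 = generations_since_divergence(0.0103)
        assert res1.generations == pytest.approx(2.80e7, rel=5e-3)
        res2 = generations_since_divergence(0.0406)
        assert res2.generations == pytest.approx(1.10e8, rel=5e-3)
        assert res1.years_low < res1.years_high

    def test_invalid_mu_rejected(self):
        with pytest.raises(ValueError):
            generations_since_divergence(0.01, mu=0.0)


class TestNjTree:
    def test_three_taxa_topology(self):
        newick = nj_tree([[0, 2, 3], [2, 0, 3], [3, 3, 0]], ["a", "b", "c"])
        assert newick.count(",") == 2
        for taxon in ("a", "b", "c"):
            assert taxon in newick

    def test_additive_four_taxon_matrix_recovered(self):
        import skbio

        # patristic distances of ((A:2,B:3):1,(C:4,D:5)) with internal edge 1
        dm = np.array([
            [0, 5, 7, 8],
            [5, 0, 8, 9],
            [7, 8, 0, 9],
            [8, 9, 9, 0],
        ], dtype=float)
        ids = ["A", "B", "C", "D"]
        tree = skbio.TreeNode.read(StringIO(nj_tree(dm, ids)))
        dists = tree.tip_tip_distances(ids)
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                assert dists[a, b] == pytest.approx(dm[i, j], abs=1e-9)

    def test_zero_distance_taxon_gets_zero_branch(self):
        import skbio

        dm = [[0, 0, 4], [0, 0, 4], [4, 4, 0]]
        tree = skbio.TreeNode.read(StringIO(nj_tree(dm, ["a", "b", "c"])))
        assert tree.tip_tip_distances(["a", "b"])["a", "b"] == pytest.approx(0.0, abs=1e-9)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            nj_tree([[0, 1, 2], [9, 0, 2], [2, 2, 0]], ["a", "b", "c"])
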
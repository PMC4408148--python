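import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from crabflow.diversity import (
    heterozygosities,
    hwe_deficit_test,
    multilocus_means,
    pairwise_fst_permutation,
    private_allelic_richness,
    rarefied_allelic_richness,
    site_filters,
    wc_f_statistics,
)
from conftest import make_matrix, random_pool_matrix


# -- independent oracles ------------------------------------------------------


def ar_exhaustive(counts, g):
    """Mean distinct-allele count over all g-subsets of the gene copies."""
    copies = [a for a, c in enumerate(counts) for _ in range(c)]
    total = Fraction(0)
    n = 0
    for combo in itertools.combinations(range(len(copies)), g):
        total += len({copies[i] for i in combo})
        n += 1
    return total / n


def ap_exhaustive_two_units(counts_a, counts_b, g):
    """Mean number of alleles in a g-subsample of unit A absent from an
    independent g-subsample of unit B (double enumeration)."""
    def pools(counts):
        return [a for a, c in enumerate(counts) for _ in range(c)]

    pa, pb = pools(counts_a), pools(counts_b)
    total = Fraction(0)
    n = 0
    for ca in itertools.combinations(range(len(pa)), g):
        sa = {pa[i] for i in ca}
        for cb in itertools.combinations(range(len(pb)), g):
            sb = {pb[i] for i in cb}
            total += len(sa - sb)
            n += 1
    return total / n


def wc_theta_oracle(pop_calls):
    """Direct transliteration of the two-level variance-component estimator,
    scalar arithmetic only."""
    alleles = sorted({a for calls in pop_calls for pair in calls for a in pair})
    r = len(pop_calls)
    A = B = C = 0.0
    n_i = [len(c) for c in pop_calls]
    nsum = sum(n_i)
    nbar = nsum / r
    nc = (nsum - sum(n**2 for n in n_i) / nsum) / (r - 1)
    for allele in alleles:
        p_i, h_i = [], []
        for calls in pop_calls:
            n = len(calls)
            count = sum(int(a == allele) + int(b == allele) for a, b in calls)
            het = sum(1 for a, b in calls if (a == allele) != (b == allele))
            p_i.append(count / (2 * n))
            h_i.append(het / n)
        pbar = sum(n * p for n, p in zip(n_i, p_i)) / nsum
        hbar = sum(n * h for n, h in zip(n_i, h_i)) / nsum
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        A, B, C = A + a, B + b, C + c
    return A / (A + B + C)


# -- heterozygosity -----------------------------------------------------------


class TestHeterozygosities:
    def test_all_homozygous(self):
        G = make_matrix([[(1, 1)], [(1, 1)]])
        het = heterozygosities(G)
        assert het.loc[0, "H_O"] == 0.0
        assert het.loc[0, "H_E"] == 0.0

    def test_hand_arithmetic_two_heterozygotes(self):
        # two individuals (a,b),(a,b): H_O = 1, H_E = (4/3) * 0.5 = 2/3
        G = make_matrix([[(1, 2)], [(1, 2)]])
        het = heterozygosities(G)
        assert het.loc[0, "H_O"] == 1.0
        assert het.loc[0, "H_E"] == pytest.approx(2 / 3)

    def test_hwe_pool_ho_near_he(self, rng):
        G = random_pool_matrix(rng, n=500, n_loci=20)
        het = heterozygosities(G)
        means = multilocus_means(het)
        assert means["H_O"] == pytest.approx(means["H_E"], abs=0.03)

    def test_missing_excluded(self):
        G = make_matrix([[(1, 2)], [(0, 0)]])
        het = heterozygosities(G)
        assert het.loc[0, "n_typed"] == 1
        assert het.loc[0, "H_O"] == 1.0


# -- Weir-Cockerham -----------------------------------------------------------


class TestWcFStatistics:
    def test_fixed_difference_theta_one(self):
        calls = np.ones((10, 4, 2), dtype=np.int32)
        calls[5:] = 2
        G = make_matrix(calls)
        res = wc_f_statistics(G, {"a": np.arange(5), "b": np.arange(5, 10)})
        assert res["F_ST"] == pytest.approx(1.0)

    def test_single_unit_hwe_fis_near_zero(self, rng):
        G = random_pool_matrix(rng, n=400, n_loci=25)
        res = wc_f_statistics(G, {"one": np.arange(400)})
        assert np.isnan(res["F_ST"])
        assert res["single_unit"]
        assert abs(res["F_IS"]) < 0.02

    def test_oracle_equivalence_small_instance(self, rng):
        for trial in range(10):
            calls = rng.integers(1, 4, size=(8, 1, 2)).astype(np.int32)
            G = make_matrix(calls)
            units = {"a": np.arange(4), "b": np.arange(4, 8)}
            res = wc_f_statistics(G, units)
            if np.isnan(res["F_ST"]):
                continue
            pop_calls = [
                [tuple(calls[i, 0]) for i in units["a"]],
                [tuple(calls[i, 0]) for i in units["b"]],
            ]
            assert res["F_ST"] == pytest.approx(wc_theta_oracle(pop_calls), abs=1e-12)

    def test_monomorphic_locus_excluded(self):
        calls = np.array([[[1, 1], [1, 2]], [[1, 1], [2, 2]],
                          [[1, 1], [1, 1]], [[1, 1], [1, 2]]], dtype=np.int32)
        G = make_matrix(calls)
        res = wc_f_statistics(G, {"a": [0, 1], "b": [2, 3]})
        per_locus = res["per_locus"]
        assert np.isnan(per_locus.loc[0, "F_ST"])  # locus 1 monomorphic


class TestPairwiseFstPermutation:
    def test_fixed_difference_extreme_p(self):
        calls = np.ones((12, 5, 2), dtype=np.int32)
        calls[6:] = 2
        G = make_matrix(calls)
        res = pairwise_fst_permutation(
            G, {"a": np.arange(6), "b": np.arange(6, 12)}, n_perm=99, seed=0
        )
        assert res["p"].loc["a", "b"] == pytest.approx(1 / 100)

    def test_identical_units_theta_near_zero(self, rng):
        G = random_pool_matrix(rng, n=60, n_loci=10)
        res = pairwise_fst_permutation(
            G, {"a": np.arange(30), "b": np.arange(30, 60)}, n_perm=99, seed=1
        )
        assert abs(res["theta"].loc["a", "b"]) < 0.03
        assert res["p"].loc["a", "b"] > 0.05

    def test_zero_permutations_error(self, rng):
        G = random_pool_matrix(rng, n=10, n_loci=3)
        with pytest.raises(ValueError):
            pairwise_fst_permutation(G, {"a": [0, 1], "b": [2, 3]}, n_perm=0)


class TestHweDeficitTest:
    def test_all_homozygotes_extreme(self):
        # 5 (a,a) + 5 (b,b) at two loci: maximal deficit
        calls = np.ones((10, 2, 2), dtype=np.int32)
        calls[5:] = 2
        G = make_matrix(calls)
        res = hwe_deficit_test(G, n_perm=999, seed=0)
        assert res["F_IS"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(1 / 1000)

    def test_monomorphic_flagged(self):
        G = make_matrix([[(1, 1)], [(1, 1)], [(1, 1)]])
        res = hwe_deficit_test(G, n_perm=99)
        assert np.isnan(res["p"]) and res["flag"]

    def test_type_i_error_calibration(self, rng):
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            G = random_pool_matrix(rng, n=40, n_loci=6)
            res = hwe_deficit_test(G, n_perm=99, seed=rep)
            if res["p"] <= 0.05:
                hits += 1
        # binomial(60, 0.05): P(hits <= 8) > 0.99
        assert hits <= 8


# -- rarefaction ----------------------------------------------------------------


class TestRarefiedAllelicRichness:
    def test_monomorphic_is_one(self):
        G = make_matrix([[(1, 1)], [(1, 1)], [(1, 1)]])
        ar = rarefied_allelic_richness(G, [0, 1, 2], g=2)
        assert ar.loc[0, "A_R"] == pytest.approx(1.0)

    def test_hand_combinatorics(self):
        # allele counts {5, 5}, g=2: 2 * (1 - C(5,2)/C(10,2)) = 14/9
        calls = np.array([[[1, 1]], [[1, 1]], [[1, 2]], [[2, 2]], [[2, 2]]],
                         dtype=np.int32)
        G = make_matrix(calls)
        ar = rarefied_allelic_richness(G, np.arange(5), g=2)
        assert ar.loc[0, "A_R"] == pytest.approx(14 / 9)

    def test_exhaustive_oracle(self, rng):
        for trial in range(15):
            n = int(rng.integers(2, 7))  # <= 12 gene copies
            calls = rng.integers(1, 4, size=(n, 1, 2)).astype(np.int32)
            G = make_matrix(calls)
            g = int(rng.integers(1, 2 * n + 1))
            ar = rarefied_allelic_richness(G, np.arange(n), g=g)
            counts = np.bincount(calls.ravel())[1:]
            oracle = ar_exhaustive(list(counts), g)
            assert ar.loc[0, "A_R"] == pytest.approx(float(oracle), abs=1e-10)

    def test_g_bounds_and_monotonicity(self, rng):
        G = random_pool_matrix(rng, n=30, n_loci=8)
        prev = None
        for g in (2, 4, 8, 16):
            ar = rarefied_allelic_richness(G, np.arange(30), g=g)
            vals = ar["A_R"].to_numpy()
            if g == 2:
                assert ((vals >= 1 - 1e-12) & (vals <= 2 + 1e-12)).all()
            if prev is not None:
                assert (vals >= prev - 1e-12).all()
            prev = vals

    def test_insufficient_copies_flagged(self):
        G = make_matrix([[(1, 2)], [(0, 0)]])
        ar = rarefied_allelic_richness(G, [0, 1], g=4)
        assert not ar.loc[0, "included"]
        assert np.isnan(ar.loc[0, "A_R"])


class TestPrivateAllelicRichness:
    def test_private_fixed_allele(self):
        # allele 2 occurs only in unit b and is fixed there
        calls = np.array([[[1, 1]], [[1, 1]], [[2, 2]], [[2, 2]]], dtype=np.int32)
        G = make_matrix(calls)
        ap = private_allelic_richness(G, {"a": [0, 1], "b": [2, 3]}, g=2)
        out = ap.set_index("unit")
        assert out.loc["b", "A_P"] == pytest.approx(1.0)
        assert out.loc["a", "A_P"] == pytest.approx(1.0)

    def test_shared_fixed_allele_contributes_zero(self):
        G = make_matrix([[(1, 1)], [(1, 1)], [(1, 1)], [(1, 1)]])
        ap = private_allelic_richness(G, {"a": [0, 1], "b": [2, 3]}, g=2)
        assert (ap["A_P"] == 0).all()

    def test_exhaustive_double_enumeration_oracle(self, rng):
        for trial in range(8):
            na, nb = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            calls = rng.integers(1, 4, size=(na + nb, 1, 2)).astype(np.int32)
            G = make_matrix(calls)
            units = {"a": np.arange(na), "b": np.arange(na, na + nb)}
            g = 2
            ap = private_allelic_richness(G, units, g=g).set_index("unit")
            n_alleles = 4
            counts_a = [int((calls[:na] == a).sum()) for a in range(1, n_alleles)]
            counts_b = [int((calls[na:] == a).sum()) for a in range(1, n_alleles)]
            oracle_a = ap_exhaustive_two_units(counts_a, counts_b, g)
            oracle_b = ap_exhaustive_two_units(counts_b, counts_a, g)
            assert ap.loc["a", "A_P"] == pytest.approx(float(oracle_a), abs=1e-10)
            assert ap.loc["b", "A_P"] == pytest.approx(float(oracle_b), abs=1e-10)

    def test_ap_bounded_by_ar(self, rng):
        G = random_pool_matrix(rng, n=40, n_loci=6)
        units = {"a": np.arange(20), "b": np.arange(20, 40)}
        ap = private_allelic_richness(G, units, g=4).set_index("unit")
        for name, idx in units.items():
            ar = rarefied_allelic_richness(G, idx, g=4)
            assert ap.loc[name, "A_P"] <= ar["A_R"].mean() + 1e-9


class TestSiteFilters:
    def test_small_site_excluded(self, rng):
        G = random_pool_matrix(rng, n=9, n_loci=4,
                               sites=["a"] * 3 + ["b"] * 6)
        res = site_filters(G)
        assert res["diversity_sites"] == ["b"]
        assert "a" in res["excluded"]

    def test_sparse_marker_excluded_from_richness_set(self):
        calls = np.ones((5, 2, 2), dtype=np.int32)
        calls[1:, 1] = 0  # locus 2 typed in only one individual
        G = make_matrix(calls, sites=["s"] * 5)
        res = site_filters(G)
        assert res["diversity_sites"] == ["s"]
        assert res["richness_sites"] == []

    def test_complete_data_identity(self, rng):
        G = random_pool_matrix(rng, n=20, n_loci=4,
                               sites=["a"] * 10 + ["b"] * 10)
        res = site_filters(G)
        assert res["diversity_sites"] == res["richness_sites"] == ["a", "b"]
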
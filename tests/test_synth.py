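import numpy as np
import pandas as pd
import pytest

from crabflow.genio import INSECT_ORDERS
from crabflow.synth import (
    DispersalConfig,
    SimulationConfig,
    attach_landscape_covariates,
    assign_hybrid_status,
    sample_cluster_frequencies,
    sample_genotypes,
    simulate_spatial_pedigree,
    simulate_visitor_observations,
)


def small_config(**kw):
    base = dict(n_wild_clusters=2, n_loci=8, alleles_per_locus=(4, 6),
                n_per_cluster=20, n_crop=10, seed=7)
    base.update(kw)
    return SimulationConfig(**base)


class TestSampleClusterFrequencies:
    def test_rows_sum_to_one(self):
        freqs = sample_cluster_frequencies(small_config())
        for fl in freqs.freqs:
            assert np.allclose(fl.sum(axis=1), 1.0)

    def test_no_drift_limit(self):
        # F -> 0: cluster frequencies approach the shared ancestral vector,
        # so any two clusters agree within 1e-2 total variation
        cfg = small_config(divergence_f=1e-6, crop_divergence_f=1e-6, n_loci=20)
        freqs = sample_cluster_frequencies(cfg)
        for fl in freqs.freqs:
            tv = 0.5 * np.abs(fl[0] - fl[1]).sum()
            assert tv < 1e-2

    def test_degenerate_f_rejected(self):
        with pytest.raises(ValueError):
            sample_cluster_frequencies(small_config(divergence_f=1.0))
        with pytest.raises(ValueError):
            sample_cluster_frequencies(small_config(divergence_f=0.0))

    def test_seed_determinism(self):
        cfg = small_config()
        t1 = sample_cluster_frequencies(cfg).to_frame()
        t2 = sample_cluster_frequencies(cfg).to_frame()
        pd.testing.assert_frame_equal(t1, t2)

    def test_theta_monte_carlo_oracle(self):
        # F = 0.5 over many replicate loci: the Weir-Cockerham multilocus
        # estimate on sampled genotypes must match the moment-based theta
        # recomputed from the same drawn (true) frequencies.
        from crabflow.diversity import wc_f_statistics
        from conftest import make_matrix

        cfg = SimulationConfig(n_wild_clusters=2, n_loci=1500,
                               alleles_per_locus=(4, 8), divergence_f=0.5,
                               crop_divergence_f=0.5, n_per_cluster=100,
                               n_crop=0, seed=11)
        freqs = sample_cluster_frequencies(cfg)
        G, _ = sample_genotypes(freqs, cfg)
        units = {"a": np.arange(100), "b": np.arange(100, 200)}
        theta = wc_f_statistics(G, units)["F_ST"]

        num = den = 0.0
        for fl in freqs.freqs:
            p1, p2 = fl[0], fl[1]
            pbar = (p1 + p2) / 2
            s2 = (p1 - p2) ** 2 / 2
            num += s2.sum()
            den += (s2 / 2 + pbar * (1 - pbar)).sum()
        theta_oracle = num / den
        assert theta == pytest.approx(theta_oracle, abs=0.02)
        # sanity: between two independently drifted pools, E[s2] = F*p*q and
        # E[pbar*qbar] = p*q*(1 - F/2), so the ratio-of-sums theta sits near F
        assert theta_oracle == pytest.approx(0.5, abs=0.05)


class TestSampleGenotypes:
    def test_all_pure_single_pool_hwe(self):
        cfg = SimulationConfig(n_wild_clusters=1, n_loci=30, n_per_cluster=300,
                               n_crop=0, seed=5)
        freqs = sample_cluster_frequencies(cfg)
        G, truth = sample_genotypes(freqs, cfg)
        assert set(truth["hybrid_class"]) == {"pure_wild"}
        # observed heterozygosity tracks 1 - sum p^2 of the generating pool
        for l in range(5):
            p = freqs.freqs[l][0]
            he_true = 1 - (p**2).sum()
            ho = (G.calls[:, l, 0] != G.calls[:, l, 1]).mean()
            assert ho == pytest.approx(he_true, abs=0.08)

    def test_f1_fixed_difference_cross(self):
        cfg = SimulationConfig(n_wild_clusters=1, n_loci=6, n_per_cluster=0,
                               n_crop=0, hybrid_spec=[((0.5, 0.5), 10, "F1")],
                               seed=3)
        freqs = sample_cluster_frequencies(cfg)
        # force fixed, disjoint alleles: wild fixed for first allele, crop for last
        for fl in freqs.freqs:
            fl[:] = 0.0
            fl[0, 0] = 1.0
            fl[1, -1] = 1.0
        G, truth = sample_genotypes(freqs, cfg)
        for l in range(G.n_loci):
            codes = freqs.allele_codes[l]
            assert (G.calls[:, l, 0] == codes[0]).all()
            assert (G.calls[:, l, 1] == codes[-1]).all()

    def test_missing_rate_binomial_bounds(self):
        cfg = small_config(missing_rate=0.15, n_per_cluster=50, n_crop=0,
                           n_loci=20)  # 2 clusters x 50 x 20 = 2000 calls
        freqs = sample_cluster_frequencies(cfg)
        G, _ = sample_genotypes(freqs, cfg)
        frac = G.missing_mask().mean()
        n_calls = G.n_individuals * G.n_loci
        half_width = 2.576 * np.sqrt(0.15 * 0.85 / n_calls)
        assert abs(frac - 0.15) < half_width

    def test_empty_design_error(self):
        cfg = small_config(n_per_cluster=0, n_crop=0)
        freqs = sample_cluster_frequencies(cfg)
        with pytest.raises(ValueError, match="empty design"):
            sample_genotypes(freqs, cfg)

    def test_ancestry_rows_sum_to_one(self):
        cfg = small_config(hybrid_spec=[((0.25, 0.25, 0.5), 5, "F1")])
        freqs = sample_cluster_frequencies(cfg)
        _, truth = sample_genotypes(freqs, cfg)
        q = truth.filter(like="q_").to_numpy()
        assert np.allclose(q.sum(axis=1), 1.0, atol=1e-12)

    def test_alleles_conserved(self):
        cfg = small_config()
        freqs = sample_cluster_frequencies(cfg)
        G, _ = sample_genotypes(freqs, cfg)
        for l in range(G.n_loci):
            observed = set(G.calls[:, l, :].ravel()) - {0}
            assert observed <= set(freqs.allele_codes[l].tolist())

    def test_determinism(self):
        cfg = small_config()
        freqs = sample_cluster_frequencies(cfg)
        G1, t1 = sample_genotypes(freqs, cfg)
        G2, t2 = sample_genotypes(freqs, cfg)
        assert G1 == G2
        pd.testing.assert_frame_equal(t1, t2)


class TestSpatialPedigree:
    def test_zero_generations_identity(self):
        cfg = small_config(dispersal=DispersalConfig(1.0, 1.0, 0))
        freqs = sample_cluster_frequencies(cfg)
        G1, t1 = simulate_spatial_pedigree(freqs, cfg, n_individuals=30)
        cfg2 = small_config(dispersal=DispersalConfig(9.0, 9.0, 0))
        G2, t2 = simulate_spatial_pedigree(freqs, cfg2, n_individuals=30)
        # founders depend only on the seed, not on the dispersal kernel
        assert G1 == G2
        assert np.allclose(t1[["x_km", "y_km"]], t2[["x_km", "y_km"]])

    def test_nonpositive_sigma_error(self):
        cfg = small_config(dispersal=DispersalConfig(0.0, 1.0, 5))
        freqs = sample_cluster_frequencies(cfg)
        with pytest.raises(ValueError, match="sigma"):
            simulate_spatial_pedigree(freqs, cfg)

    def test_positions_stay_in_rectangle(self):
        cfg = small_config(dispersal=DispersalConfig(5.0, 5.0, 10),
                           extent_km=(10.0, 10.0))
        freqs = sample_cluster_frequencies(cfg)
        _, truth = simulate_spatial_pedigree(freqs, cfg, n_individuals=40)
        assert truth["x_km"].between(0, 10).all()
        assert truth["y_km"].between(0, 10).all()

    def test_alleles_from_founder_pool(self):
        cfg = small_config(dispersal=DispersalConfig(2.0, 1.0, 8))
        freqs = sample_cluster_frequencies(cfg)
        G, _ = simulate_spatial_pedigree(freqs, cfg, n_individuals=30, pool=1)
        for l in range(G.n_loci):
            observed = set(G.calls[:, l, :].ravel()) - {0}
            assert observed <= set(freqs.allele_codes[l].tolist())


class TestLandscapeCovariates:
    def test_zero_betas_equal_rates(self):
        _, probs = attach_landscape_covariates([f"s{i}" for i in range(10)],
                                               (0.0, 0.0, 0.0), seed=1)
        assert probs.nunique() == 1

    def test_interaction_monotonicity(self):
        sites = [f"s{i}" for i in range(30)]
        tab, probs = attach_landscape_covariates(sites, (0.0, 0.0, 1.0), seed=2)
        zd = (tab["apple_density"] - tab["apple_density"].mean()) / tab["apple_density"].std()
        zn = (tab["n_orchards"] - tab["n_orchards"].mean()) / tab["n_orchards"].std()
        hh = (zd > 0.5) & (zn > 0.5)
        hl = (zd > 0.5) & (zn < -0.5)
        assert probs[hh.to_numpy()].mean() > probs[hl.to_numpy()].mean()

    def test_count_area_correlation_near_target(self):
        tab, _ = attach_landscape_covariates([f"s{i}" for i in range(20)],
                                             seed=3, target_corr=0.9)
        r = np.corrcoef(tab["n_orchards"], tab["orchard_area"])[0, 1]
        assert abs(r - 0.9) < 0.1

    def test_needs_two_sites(self):
        with pytest.raises(ValueError, match="two sites"):
            attach_landscape_covariates(["only"], seed=0)

    def test_covariates_non_negative(self):
        tab, _ = attach_landscape_covariates([f"s{i}" for i in range(15)], seed=4)
        assert (tab[["apple_density", "n_orchards", "orchard_area"]] >= 0).all().all()

    def test_assign_hybrid_status(self):
        sites = ["a", "b"]
        probs = pd.Series([0.0, 1.0], index=sites)
        status = assign_hybrid_status(pd.Series(["a", "a", "b", "b"]), probs, seed=0)
        assert list(status) == [False, False, True, True]


class TestVisitorObservations:
    def test_schema_and_total(self):
        tab = simulate_visitor_observations(management_effect=1.0, n_obs=306, seed=0)
        assert list(tab.columns) == ["record_id", "taxon_id", "insect_order",
                                     "management_class"]
        assert len(tab) == 306
        assert set(tab["insect_order"]) <= set(INSECT_ORDERS)

    def test_zero_effect_equal_richness_in_expectation(self):
        rich = {"intensive": [], "extensive": []}
        for s in range(30):
            tab = simulate_visitor_observations(management_effect=0.0,
                                                n_obs=400, seed=s)
            for mclass, sub in tab.groupby("management_class"):
                rich[mclass].append(sub["taxon_id"].nunique())
        a, b = np.mean(rich["intensive"]), np.mean(rich["extensive"])
        assert abs(a - b) / max(a, b) < 0.1

    def test_large_effect_floors_at_one_taxon_per_order(self):
        tab = simulate_visitor_observations(management_effect=50.0, n_obs=500, seed=1)
        intensive = tab[tab["management_class"] == "intensive"]
        per_order = intensive.groupby("insect_order")["taxon_id"].nunique()
        assert (per_order == 1).all()

    def test_unknown_order_rejected(self):
        with pytest.raises(ValueError, match="order"):
            simulate_visitor_observations(rates_by_order={"Araneae": 5.0})
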
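"""Synthetic herd generator: pedigree structure, gene dropping, liability
phenotypes, and dataset round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import temprrm as t
from temprrm.legendre import CoeffCovariances
from temprrm.pedigree import sort_pedigree
from temprrm.simulate import (SimConfig, gene_drop_genotypes, read_dataset,
                              simulate_pedigree, simulate_phenotypes,
                              write_dataset)


class TestSimulatePedigree:
    def test_founders_only(self):
        ped = simulate_pedigree(SimConfig(n_founders=2, n_generations=0))
        assert len(ped) == 2
        assert (ped[["sire", "dam"]] == 0).all().all()

    def test_deterministic_under_seed(self):
        cfg = SimConfig(n_founders=10, n_generations=3, seed=5)
        pd.testing.assert_frame_equal(simulate_pedigree(cfg),
                                      simulate_pedigree(cfg))

    def test_parents_from_earlier_generations(self, small_herd):
        ped = small_herd["ped"]
        gen = ped.set_index("animal")["generation"]
        for row in ped.itertuples():
            for par in (row.sire, row.dam):
                if par:
                    assert gen[par] < row.generation

    def test_topological_sort_succeeds(self, small_herd):
        pidx = sort_pedigree(small_herd["ped"])
        for i in range(pidx.n):
            assert pidx.sire[i] < i and pidx.dam[i] < i

    def test_single_founder_rejected(self):
        with pytest.raises(ValueError):
            simulate_pedigree(SimConfig(n_founders=1, n_generations=1))


class TestGeneDrop:
    def test_monomorphic_transmission(self):
        # force fixation: allele frequency range (1, 1) makes all founders AA
        cfg = SimConfig(n_founders=6, n_generations=2,
                        allele_freq_range=(1.0, 1.0), n_snps=10, seed=1)
        ped = simulate_pedigree(cfg)
        M, _, _ = gene_drop_genotypes(ped, cfg)
        assert (M.to_numpy() == 1).all()

    def test_heterozygosity_matches_binomial_expectation(self):
        cfg = SimConfig(n_founders=400, n_generations=0,
                        allele_freq_range=(0.5, 0.5), n_snps=200, seed=2)
        ped = simulate_pedigree(cfg)
        M, _, _ = gene_drop_genotypes(ped, cfg)
        het = (M.to_numpy() == 0).mean()
        se = np.sqrt(0.5 * 0.5 / M.size)
        assert abs(het - 0.5) < 3 * se

    def test_full_sib_relationship_near_half(self):
        # many full sibs from one founder pair; VanRaden scaling against the
        # pedigree expectation of 0.5
        rows = [(1, 0, 0, 0, "M"), (2, 0, 0, 0, "F")] + \
               [(i, 1, 2, 1, "F") for i in range(3, 43)]
        ped = pd.DataFrame(rows, columns=["animal", "sire", "dam",
                                          "generation", "sex"])
        cfg = SimConfig(n_founders=2, n_generations=1, n_snps=4000, seed=3,
                        allele_freq_range=(0.2, 0.8))
        M, _, founder_p = gene_drop_genotypes(ped, cfg)
        from temprrm.genomic import build_G
        # center by the true founder frequencies: with only two founders the
        # observed frequencies would re-center the family to zero
        G = build_G(M, p=founder_p).toarray()
        sib = G[2:, 2:]
        off = sib[~np.eye(sib.shape[0], dtype=bool)]
        assert abs(off.mean() - 0.5) < 0.1

    def test_deterministic_under_seed(self, small_cfg, small_herd):
        M2, map2, _ = gene_drop_genotypes(small_herd["ped"], small_cfg)
        pd.testing.assert_frame_equal(small_herd["geno"][0], M2)


class TestSimulatePhenotypes:
    def null_cfg(self, thresholds=(0.0, 1.0, 2.0)):
        cc = CoeffCovariances(G_u=1e-12 * np.eye(2), R_p=1e-12 * np.eye(2),
                              R_q=1e-12 * np.eye(2), sigma2_e=1.0)
        return SimConfig(n_founders=600, n_generations=0, n_snps=2,
                        true_components=cc, thresholds=thresholds,
                        fixed_effects={"conception": {"nat": 0.0, "et": 0.0},
                                       "hys": {"h": 0.0}},
                        mean_records=2.5, min_records=1, seed=4)

    def test_null_model_category_probabilities(self):
        cfg = self.null_cfg()
        ped = simulate_pedigree(cfg)
        pheno, _ = simulate_phenotypes(ped, cfg)
        # all effects null, sigma_e = 1: P(score=1) = Phi(0) = 0.5
        p1 = (pheno["score"] == 1).mean()
        se = np.sqrt(0.25 / len(pheno))
        assert abs(p1 - norm.cdf(0.0)) < 3 * se
        p2 = (pheno["score"] == 2).mean()
        assert abs(p2 - (norm.cdf(1) - norm.cdf(0))) < 3 * se

    def test_zero_genetic_variance_no_parent_offspring_signal(self):
        cfg = self.null_cfg()
        cfg2 = SimConfig(**{**cfg.__dict__, "n_founders": 150,
                            "n_generations": 2, "seed": 8})
        ped = simulate_pedigree(cfg2)
        pheno, _ = simulate_phenotypes(ped, cfg2)
        means = pheno.groupby("animal")["score"].mean()
        dams = ped.set_index("animal")["dam"]
        pairs = [(means[a], means[dams[a]]) for a in means.index
                 if dams.get(a, 0) in means.index and dams[a] != 0]
        x, y = np.array(pairs).T
        slope = np.polyfit(x, y, 1)[0] if len(pairs) > 10 else 0.0
        assert abs(slope) < 0.2

    def test_realized_intercept_variance_matches_truth(self):
        cfg = SimConfig(n_founders=1500, n_generations=1, n_snps=2, seed=6)
        ped = simulate_pedigree(cfg)
        _, truth = simulate_phenotypes(ped, cfg)
        v = truth["u_intercept"].var()
        se = 0.396 * np.sqrt(2 / len(truth))  # chi-square SE at weak relatedness
        assert abs(v - 0.396) < 3 * se

    def test_genetic_correlation_of_truth(self):
        cfg = SimConfig(n_founders=2000, n_generations=0, n_snps=2, seed=9)
        ped = simulate_pedigree(cfg)
        _, truth = simulate_phenotypes(ped, cfg)
        r = np.corrcoef(truth["u_intercept"], truth["u_slope"])[0, 1]
        assert abs(r - 0.744) < 3 / np.sqrt(len(truth))

    def test_increasing_thresholds_enforced(self):
        with pytest.raises(ValueError):
            SimConfig(thresholds=(0.0, 1.0, 0.5))

    def test_age_schedule_respects_interval_rule(self, small_herd):
        gaps = small_herd["pheno"].sort_values(["animal", "age_days"]) \
            .groupby("animal")["age_days"].diff().dropna()
        assert (gaps >= 268).all()

    def test_bit_reproducible(self, small_cfg, small_herd):
        pheno2, truth2 = simulate_phenotypes(small_herd["ped"], small_cfg)
        pd.testing.assert_frame_equal(small_herd["pheno"], pheno2)
        pd.testing.assert_frame_equal(small_herd["truth"], truth2)


class TestDatasetRoundtrip:
    def test_roundtrip_identity(self, small_herd, tmp_path):
        write_dataset(small_herd["ped"], small_herd["geno"],
                      small_herd["pheno"], tmp_path,
                      truth=small_herd["truth"],
                      components=small_herd["cfg"].true_components,
                      thresholds=small_herd["cfg"].thresholds)
        back = read_dataset(tmp_path)
        pd.testing.assert_frame_equal(back["pedigree"], small_herd["ped"])
        pd.testing.assert_frame_equal(back["phenotypes"], small_herd["pheno"],
                                      check_dtype=False)
        pd.testing.assert_frame_equal(back["genotypes"], small_herd["geno"][0],
                                      check_dtype=False)
        assert back["truth_components"]["sigma2_e"] == pytest.approx(0.129)

    def test_truth_schema(self, small_herd, tmp_path):
        write_dataset(small_herd["ped"], None, small_herd["pheno"], tmp_path,
                      truth=small_herd["truth"])
        back = read_dataset(tmp_path)
        assert {"animal", "u_intercept", "u_slope"} <= set(back["truth"].columns)

    def test_empty_phenotypes_ok(self, small_herd, tmp_path):
        empty = small_herd["pheno"].iloc[0:0]
        write_dataset(small_herd["ped"], None, empty, tmp_path)
        assert read_dataset(tmp_path)["phenotypes"].empty

    def test_identifier_mismatch_rejected(self, small_herd, tmp_path):
        bad = small_herd["pheno"].copy()
        bad.loc[bad.index[0], "animal"] = 999999
        with pytest.raises(ValueError, match="absent from pedigree"):
            write_dataset(small_herd["ped"], None, bad, tmp_path)
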
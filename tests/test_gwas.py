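"""GWAS back-solving: SNP effects from GEBV, age transforms, sliding
windows, variance explained, selection, and interval overlap."""

import numpy as np
import pandas as pd
import pytest

from temprrm.gwas import (backsolve_snp_effects, interval_overlap, read_bed,
                          select_top_windows, snp_effects_by_age,
                          window_effects, window_variance_explained)
from temprrm.legendre import LegendreBasis

SQ05, SQ15 = np.sqrt(0.5), np.sqrt(1.5)


def geno(values, animals=None, snps=None):
    values = np.asarray(values, dtype=float)
    animals = animals or [f"a{i}" for i in range(values.shape[0])]
    snps = snps or [f"s{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(animals, name="animal"),
                        columns=snps)


def gebv_frame(values, animals):
    return pd.DataFrame(np.asarray(values, dtype=float), index=animals,
                        columns=["intercept", "slope"][:np.shape(values)[1]])


class TestBacksolve:
    def test_zero_gebv_zero_effects(self):
        M = geno(np.eye(3) - 0)
        g = gebv_frame(np.zeros((3, 2)), list(M.index))
        eff = backsolve_snp_effects(M, g, p=np.full(3, 0.5))
        assert np.all(eff.to_numpy() == 0)

    def test_scalar_inversion(self):
        M = geno([[1.0]])
        g = gebv_frame([[0.4]], ["a0"])
        eff = backsolve_snp_effects(M, g, p=np.array([0.5]))
        assert eff.iloc[0, 0] == pytest.approx(0.4)

    def test_projection_reproduces_gebv(self):
        # GEBV constructed inside the row space of the centered genotypes:
        # the projection must reproduce them exactly
        rng = np.random.default_rng(0)
        M = geno(rng.integers(-1, 2, size=(12, 60)))
        p = (M.to_numpy() + 1).mean(axis=0) / 2
        Z = M.to_numpy() - (2 * p - 1)
        g = gebv_frame(Z @ rng.standard_normal((60, 2)) * 0.1, list(M.index))
        eff = backsolve_snp_effects(M, g, p=p)
        assert np.allclose(Z @ eff.to_numpy(), g.to_numpy(), atol=1e-8)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        M = geno(rng.integers(-1, 2, size=(8, 30)))
        p = (M.to_numpy() + 1).mean(axis=0) / 2
        g = gebv_frame(rng.standard_normal((8, 2)), list(M.index))
        e1 = backsolve_snp_effects(M, g, p=p)
        e2 = backsolve_snp_effects(M, 3.0 * g, p=p)
        assert np.allclose(3.0 * e1.to_numpy(), e2.to_numpy())


class TestAgeTransform:
    basis = LegendreBasis()
    ages = [760, 2444, 4128]

    def test_zero_slope_constant_profile(self):
        eff = pd.DataFrame({"intercept": [2.0], "slope": [0.0]},
                           index=["s1"])
        out = snp_effects_by_age(eff, self.basis, self.ages)
        assert np.allclose(out.to_numpy(), SQ05 * 2.0)

    def test_zero_coefficients_zero_profile(self):
        eff = pd.DataFrame({"intercept": [0.0], "slope": [0.0]}, index=["s1"])
        out = snp_effects_by_age(eff, self.basis, self.ages)
        assert np.all(out.to_numpy() == 0)

    def test_endpoint_difference_closed_form(self):
        eff = pd.DataFrame({"intercept": [0.3], "slope": [0.7]}, index=["s1"])
        out = snp_effects_by_age(eff, self.basis, [760, 4128]).to_numpy()[0]
        assert out[1] - out[0] == pytest.approx(2 * SQ15 * 0.7)

    def test_docility_sign_flag_negates(self):
        eff = pd.DataFrame({"intercept": [0.3], "slope": [0.7]}, index=["s1"])
        a = snp_effects_by_age(eff, self.basis, self.ages)
        b = snp_effects_by_age(eff, self.basis, self.ages, docility_sign=True)
        assert np.allclose(a.to_numpy(), -b.to_numpy())


def snp_map_one_chrom(n, chrom=1, start=1):
    return pd.DataFrame({"snp": [f"s{j}" for j in range(n)],
                         "chrom": chrom,
                         "pos": start + 1000 * np.arange(n)})


class TestWindows:
    def test_sliding_sums(self):
        eff = pd.DataFrame({"e": [1, 2, 3, 4, 5, 6.0]},
                           index=[f"s{j}" for j in range(6)])
        out = window_effects(eff, snp_map_one_chrom(6), size=5)
        assert out["e"].tolist() == [15.0, 20.0]

    def test_zero_effects_zero_windows(self):
        eff = pd.DataFrame({"e": np.zeros(7)},
                           index=[f"s{j}" for j in range(7)])
        out = window_effects(eff, snp_map_one_chrom(7), size=5)
        assert (out["e"] == 0).all()

    def test_windows_never_span_chromosomes(self):
        smap = pd.concat([snp_map_one_chrom(5, chrom=1),
                          snp_map_one_chrom(5, chrom=2).assign(
                              snp=[f"t{j}" for j in range(5)])],
                         ignore_index=True)
        eff = pd.DataFrame({"e": np.arange(10.0)},
                           index=list(smap["snp"]))
        out = window_effects(eff, smap, size=5)
        assert len(out) == 2
        assert out["chrom"].tolist() == [1, 2]

    def test_short_chromosome_single_window_warned(self):
        eff = pd.DataFrame({"e": [1.0, 2.0]}, index=["s0", "s1"])
        with pytest.warns(UserWarning, match="fewer than"):
            out = window_effects(eff, snp_map_one_chrom(2), size=5)
        assert len(out) == 1

    def test_telescoping_identity(self):
        rng = np.random.default_rng(2)
        vals = rng.standard_normal(40)
        eff = pd.DataFrame({"e": vals}, index=[f"s{j}" for j in range(40)])
        out = window_effects(eff, snp_map_one_chrom(40), size=5, step=1)
        diffs = np.diff(out["e"].to_numpy())
        expected = vals[5:] - vals[:-5]
        assert np.allclose(diffs, expected)


class TestWindowVariance:
    def test_zero_effect_window(self):
        rng = np.random.default_rng(3)
        M = geno(rng.integers(-1, 2, size=(30, 5)))
        eff = pd.DataFrame({"intercept": np.zeros(5)}, index=list(M.columns))
        out = window_variance_explained(M, eff, snp_map_one_chrom(5),
                                        {"intercept": 0.4}, size=5)
        assert out["pct_var_intercept"].iloc[0] == 0.0

    def test_single_snp_window_hand_formula(self):
        rng = np.random.default_rng(4)
        M = geno(rng.integers(-1, 2, size=(200, 1)))
        a, total = 0.3, 0.5
        eff = pd.DataFrame({"intercept": [a]}, index=["s0"])
        out = window_variance_explained(M, eff, snp_map_one_chrom(1),
                                        {"intercept": total}, size=1)
        p = (M.to_numpy() + 1).mean() / 2
        z = M.to_numpy()[:, 0] - (2 * p - 1)
        expected = 100 * a ** 2 * np.var(z) / total
        assert out["pct_var_intercept"].iloc[0] == pytest.approx(expected)

    def test_disjoint_windows_sum_to_100_without_ld(self):
        rng = np.random.default_rng(5)
        n, m = 1500, 50
        p = rng.uniform(0.3, 0.7, m)
        vals = (rng.random((n, m)) < p).astype(int) + \
               (rng.random((n, m)) < p).astype(int) - 1
        M = geno(vals)
        eff_vals = rng.standard_normal(m) * 0.05
        eff = pd.DataFrame({"intercept": eff_vals}, index=list(M.columns))
        pf = (vals + 1).mean(axis=0) / 2
        Z = vals - (2 * pf - 1)
        total = float(np.var(Z @ eff_vals))
        out = window_variance_explained(M, eff, snp_map_one_chrom(m),
                                        {"intercept": total}, size=5, step=5)
        assert out["pct_var_intercept"].sum() == pytest.approx(100.0, abs=5.0)


class TestSelection:
    def windows(self):
        return pd.DataFrame({
            "window": [0, 1, 2, 3],
            "chrom": [1, 1, 1, 2],
            "start_pos": [1, 1001, 6001, 1],
            "end_pos": [5000, 6000, 9000, 4000],
            "first_index": [0, 1, 6, 10],
            "last_index": [4, 5, 9, 14],
            "e": [3.0, -4.0, 1.0, 2.0],
        })

    def test_n_larger_than_count_returns_all(self):
        out = select_top_windows(self.windows(), "e", n=10)
        assert len(out) == 3  # windows 0 and 1 overlap; larger |e| wins

    def test_greedy_non_overlap(self):
        out = select_top_windows(self.windows(), "e", n=2)
        assert out["window"].tolist() == [1, 3]  # |-4| first, then chrom 2

    def test_min_pct_threshold_empty(self):
        w = self.windows().assign(e=[0.19, 0.1, 0.05, 0.11])
        out = select_top_windows(w, "e", mode="min_pct", pct=0.20)
        assert out.empty

    def test_min_pct_keeps_above_threshold(self):
        w = self.windows().assign(e=[0.25, 0.1, 0.3, 0.21])
        out = select_top_windows(w, "e", mode="min_pct", pct=0.20)
        assert set(out["window"]) == {0, 2, 3}


class TestIntervalOverlap:
    def windows(self):
        return pd.DataFrame({"window": [0], "chrom": [1],
                             "start_pos": [100], "end_pos": [200]})

    def test_basic_overlap(self):
        ann = pd.DataFrame({"chrom": [1], "start": [150], "end": [160],
                            "name": ["iv"]})
        out = interval_overlap(self.windows(), ann)
        assert len(out) == 1
        assert out["overlap_bp"].item() == 10

    def test_adjacent_half_open_excluded(self):
        # window [100, 200] 1-based inclusive = [99, 200) 0-based half-open
        ann = pd.DataFrame({"chrom": [1, 1], "start": [200, 90],
                            "end": [250, 99], "name": ["right", "left"]})
        out = interval_overlap(self.windows(), ann)
        assert out.empty

    def test_random_set_matches_bruteforce(self):
        rng = np.random.default_rng(6)
        win = pd.DataFrame({
            "window": range(15), "chrom": rng.integers(1, 4, 15),
            "start_pos": rng.integers(1, 500, 15)})
        win["end_pos"] = win["start_pos"] + rng.integers(10, 100, 15)
        ann = pd.DataFrame({
            "chrom": rng.integers(1, 4, 20),
            "start": rng.integers(0, 500, 20), "name": [f"iv{i}" for i in range(20)]})
        ann["end"] = ann["start"] + rng.integers(1, 120, 20)
        got = interval_overlap(win, ann)
        expected = 0
        for _, w in win.iterrows():
            for _, a in ann.iterrows():
                if w["chrom"] != a["chrom"]:
                    continue
                if min(w["end_pos"], a["end"]) - max(w["start_pos"] - 1, a["start"]) > 0:
                    expected += 1
        assert len(got) == expected

    def test_malformed_bed_line_number(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("1\t10\t20\n1\tx\t30\n")
        with pytest.raises(ValueError, match="line 2"):
            read_bed(path)

    def test_read_bed_roundtrip(self, tmp_path):
        path = tmp_path / "ok.bed"
        path.write_text("# comment\n1\t10\t20\tgeneA\n2\t5\t9\n")
        out = read_bed(path)
        assert out["name"].tolist() == ["geneA", "iv3"]
        assert out["end"].tolist() == [20, 9]
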
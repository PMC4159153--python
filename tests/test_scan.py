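"""Thresholds, bitwise encoding, marginal scan, pair tests, LD, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from episcan import synthdata as sd
from episcan.containers import GenotypeMatrix, make_marker_map, round_half_up
from episcan.scan import (Thresholds, classify_pairs, derive_thresholds,
                          encode_bitwise, ld_r2, marginal_scan, pair_full_test,
                          pair_screen, scan_pairs)


class TestThresholds:
    @pytest.mark.parametrize("m,k,t_full,t_marg", [
        (514662, 166, 3.8e-13, 5.9e-10),   # the published cohort's numbers
        (2, 1, 5.0e-02, 5.0e-02),
        (1000, 10, 1.0e-07, 5.0e-06),
    ])
    def test_reported_two_significant_figures(self, m, k, t_full, t_marg):
        t = derive_thresholds(m, k)
        assert t.t_full == pytest.approx(t_full, rel=1e-9)
        assert t.t_marginal == pytest.approx(t_marg, rel=1e-9)

    def test_raw_values_exact_arithmetic(self):
        t = derive_thresholds(1000, 10)
        assert t.t_full_raw == pytest.approx(0.05 / 499500, rel=1e-12)
        assert t.t_marginal_raw == pytest.approx(0.05 / 9990, rel=1e-12)
        assert t.t_full_raw == pytest.approx(1.001001e-07, rel=1e-5)
        assert t.t_marginal_raw == pytest.approx(5.005005e-06, rel=1e-5)

    def test_zero_marginals_leaves_marginal_threshold_absent(self):
        t = derive_thresholds(100, 0)
        assert t.t_marginal is None and t.t_marginal_raw is None

    @given(m=st.integers(min_value=168, max_value=10**7),
           k=st.integers(min_value=1, max_value=166))
    @settings(max_examples=50, deadline=None)
    def test_threshold_monotonicity(self, m, k):
        """Ordering t_full < t_marginal < t_local holds whenever the marginal
        set is a small fraction of the panel (2k < m) and the marginal scan
        is larger than 0.05/1e-5 tests ((m-1)k > 5000), as in any
        genome-scale configuration."""
        from hypothesis import assume

        assume(2 * k < m and (m - 1) * k > 5000)
        t = derive_thresholds(m, k)
        assert t.t_full_raw < t.t_marginal_raw < t.t_local


class TestBitwiseEncoding:
    def test_round_trip_lossless(self):
        rng = np.random.default_rng(0)
        geno = rng.choice([-1, 0, 1, 2], p=[0.05, 0.45, 0.35, 0.15],
                          size=(83, 17)).astype(np.int8)
        bitg = encode_bitwise(geno)
        assert np.array_equal(bitg.decode(), geno)

    def test_popcounts_equal_genotype_counts(self):
        rng = np.random.default_rng(1)
        geno = rng.choice([-1, 0, 1, 2], size=(64, 5)).astype(np.int8)
        bitg = encode_bitwise(geno)
        for j in range(5):
            expected = [(geno[:, j] == k).sum() for k in range(3)]
            assert list(bitg.counts(j)) == expected

    def test_plane_ands_reproduce_pair_contingency(self):
        """AND/popcount cells equal a naive nested-loop cell counter."""
        rng = np.random.default_rng(2)
        geno = rng.choice([-1, 0, 1, 2], size=(121, 4)).astype(np.int8)
        bitg = encode_bitwise(geno)
        for i, j in [(0, 1), (1, 3), (2, 0)]:
            naive = np.zeros((3, 3), dtype=int)
            for s in range(121):
                a, b = geno[s, i], geno[s, j]
                if a >= 0 and b >= 0:
                    naive[a, b] += 1
            assert np.array_equal(bitg.cross_counts(i, j), naive)

    def test_planes_disjoint_union_is_called_mask(self):
        rng = np.random.default_rng(3)
        geno = rng.choice([-1, 0, 1, 2], size=(40, 3)).astype(np.int8)
        bitg = encode_bitwise(geno)
        for j in range(3):
            union = bitg.planes[j, 0] | bitg.planes[j, 1] | bitg.planes[j, 2]
            assert np.array_equal(union, bitg.called[j])
            inter = (bitg.planes[j, 0] & bitg.planes[j, 1]) | \
                    (bitg.planes[j, 0] & bitg.planes[j, 2]) | \
                    (bitg.planes[j, 1] & bitg.planes[j, 2])
            assert not inter.any()


class TestMarginalScan:
    def test_identity_covariance_equals_ols_score_test(self, planted_cohort):
        g, y, _, _ = planted_cohort
        res = marginal_scan(y, g)
        # OLS regression oracle per SNP
        for j in [0, 5, 17]:
            d = g.genotypes[:, j].astype(float)
            mask = d >= 0
            dc = d[mask] - d[mask].mean()
            yc = y[mask] - y[mask].mean()
            chi2 = (dc @ yc) ** 2 / (dc @ dc * (yc @ yc) / mask.sum())
            assert res["chi2"][j] == pytest.approx(chi2, rel=1e-10)

    def test_null_pvalues_uniform(self):
        c = sd.simulate_cohort(400, 300, seed=8, spacing_bp=200_000)
        res = marginal_scan(c.phenotype["trait"].to_numpy(), c.genotypes)
        ks = stats.kstest(res["p"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_planted_additive_snp_flagged_marginal(self):
        markers = sd.uniform_marker_map(20, spacing_bp=100_000)
        panel = sd.simulate_haplotypes(6000, markers, maf_range=(0.3, 0.4), seed=9)
        g, _ = sd.simulate_genotypes(panel, 5000, seed=10)
        p = g.allele_freq()[7]
        a = sd.additive_effect_for_variance(p, 0.045 / (1 - 0.045))
        ph = sd.simulate_phenotype(g, sd.EffectSpec(marginal={g.markers.snp_id[7]: (a, 0.0)}),
                                   seed=11)
        res = marginal_scan(ph["trait"].to_numpy(), g)
        # noncentral chi2 power at this effect and n is ~1 at 5e-8
        assert bool(res["marginal"][7])

    def test_monomorphic_snp_gets_nan(self):
        c = sd.simulate_cohort(100, 10, seed=12)
        c.genotypes.genotypes[:, 4] = 0
        res = marginal_scan(c.phenotype["trait"].to_numpy(), c.genotypes)
        assert np.isnan(res["p"][4])

    def test_explicit_identity_matrix_matches_default(self, planted_cohort):
        g, y, _, _ = planted_cohort
        sub = g.subset(snp_mask=np.arange(g.n_snps) < 10)
        a = marginal_scan(y, sub)
        b = marginal_scan(y, sub, V=np.eye(g.n_samples))
        # complete-genotype SNPs agree between vectorised and GLS paths
        complete = sub.called.all(axis=0)
        assert a["chi2"][complete].to_numpy() == pytest.approx(
            b["chi2"][complete].to_numpy(), rel=1e-8)


class TestPairTests:
    def test_constant_trait_screen_p_one(self, small_cohort):
        g = small_cohort.genotypes
        y = np.zeros(g.n_samples)
        scr = pair_screen(g, y, window="local", emit_p=1.0)
        assert (scr["p_screen"] == 1.0).all()

    def test_screen_equals_full_without_missingness(self):
        c = sd.simulate_cohort(800, 30, seed=13, missing_rate=0.0)
        g, y = c.genotypes, c.phenotype["trait"].to_numpy()
        scr = pair_screen(g, y, window="all", emit_p=1.0)
        rng = np.random.default_rng(0)
        for k in rng.choice(len(scr), 40, replace=False):
            row = scr.iloc[k]
            full = pair_full_test(g.dosage(row["snp1"]), g.dosage(row["snp2"]), y)
            assert row["p_screen"] == pytest.approx(full["p_full"], abs=1e-10)

    def test_balanced_two_way_anova_oracle(self):
        """Hand-computed sums of squares on a balanced 3x3 layout."""
        reps = 4
        cell_means = np.array([[1.0, 2.0, 3.0],
                               [2.0, 4.0, 4.0],
                               [3.0, 4.0, 8.0]])
        noise = np.array([-1.0, 1.0, -2.0, 2.0]) * 0.5
        g1, g2, y = [], [], []
        for a in range(3):
            for b in range(3):
                for r in range(reps):
                    g1.append(a); g2.append(b); y.append(cell_means[a, b] + noise[r])
        g1, g2, y = np.array(g1, float), np.array(g2, float), np.array(y)
        n = y.size
        grand = y.mean()
        ss_a = sum((y[g1 == a].mean() - grand) ** 2 * (g1 == a).sum() for a in range(3))
        ss_b = sum((y[g2 == b].mean() - grand) ** 2 * (g2 == b).sum() for b in range(3))
        ss_cells = sum((y[(g1 == a) & (g2 == b)].mean() - grand) ** 2 * reps
                       for a in range(3) for b in range(3))
        ss_within = sum((y[(g1 == a) & (g2 == b)] - y[(g1 == a) & (g2 == b)].mean()) ** 2
                        for a in range(3) for b in range(3)).sum()
        ss_ab = ss_cells - ss_a - ss_b
        f_hand = (ss_ab / 4) / (ss_within / (n - 9))
        p_hand = stats.f.sf(f_hand, 4, n - 9)
        res = pair_full_test(g1, g2, y)
        assert res["F"] == pytest.approx(f_hand, rel=1e-10)
        assert res["p_full"] == pytest.approx(p_hand, rel=1e-9)
        assert res["df_int"] == 4

    def test_null_pair_p_uniform_over_replicates(self):
        rng = np.random.default_rng(14)
        pvals = []
        for _ in range(300):
            g1 = rng.choice(3, 300, p=[0.49, 0.42, 0.09]).astype(float)
            g2 = rng.choice(3, 300, p=[0.36, 0.48, 0.16]).astype(float)
            y = rng.normal(size=300)
            pvals.append(pair_full_test(g1, g2, y)["p_full"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_irrelevant_background_changes_little(self):
        rng = np.random.default_rng(15)
        n = 4000
        g1 = rng.choice(3, n, p=[0.49, 0.42, 0.09]).astype(float)
        g2 = rng.choice(3, n, p=[0.36, 0.48, 0.16]).astype(float)
        y = 0.3 * g1 * g2 + rng.normal(size=n)
        p0 = pair_full_test(g1, g2, y)["p_full"]
        p1 = pair_full_test(g1, g2, y, background=rng.normal(size=n))["p_full"]
        assert np.log10(max(p1, 1e-300)) == pytest.approx(
            np.log10(max(p0, 1e-300)), abs=0.15)

    def test_empty_cells_reduce_df(self):
        rng = np.random.default_rng(16)
        g1 = rng.choice([0, 1], 500).astype(float)  # no hom-alt genotypes
        g2 = rng.choice(3, 500).astype(float)
        y = rng.normal(size=500)
        res = pair_full_test(g1, g2, y)
        assert res["df_int"] == 2  # 6 cells - (1 + 1 + 2) main parameters


class TestLd:
    def test_identical_vectors_r2_one(self):
        g = np.array([0, 1, 2, 1, 0, 2, 1], dtype=float)
        assert ld_r2(g, g) == pytest.approx(1.0)

    def test_haplotype_frequency_fixture_r2(self):
        """Composite-LD closed form: haplotype frequencies built for r2 = 0.23."""
        pA, pB, r2_target = 0.30, 0.40, 0.23
        D = np.sqrt(r2_target * pA * (1 - pA) * pB * (1 - pB))
        hap_p = np.array([
            (1 - pA) * (1 - pB) + D,   # 00
            (1 - pA) * pB - D,         # 01
            pA * (1 - pB) - D,         # 10
            pA * pB + D,               # 11
        ])
        assert hap_p.min() > 0
        rng = np.random.default_rng(17)
        n = 9000
        h = rng.choice(4, size=(n, 2), p=hap_p)
        g1 = (h[:, 0] >= 2).astype(float) + (h[:, 1] >= 2)
        g2 = (h[:, 0] % 2).astype(float) + (h[:, 1] % 2)
        assert ld_r2(g1, g2) == pytest.approx(0.23, abs=0.02)

    def test_independent_snps_near_null_bias(self):
        rng = np.random.default_rng(18)
        vals = [ld_r2(rng.choice(3, 500).astype(float),
                      rng.choice(3, 500).astype(float)) for _ in range(200)]
        assert np.mean(vals) == pytest.approx(1 / 500, abs=1.5e-3)

    def test_monomorphic_undefined(self):
        assert np.isnan(ld_r2(np.zeros(10), np.arange(10) % 3))


class TestClassification:
    def _thresholds(self):
        return derive_thresholds(514662, 166)

    def test_published_pair_distance(self):
        markers = make_marker_map(["rs731069", "rs10939766"], ["4", "4"],
                                  [10_152_431, 10_204_970])
        pairs = pd.DataFrame({"snp1": ["rs10939766"], "snp2": ["rs731069"],
                              "p_full": [1.5e-02], "p_screen": [1.5e-02]})
        out = classify_pairs(pairs, self._thresholds(), [], markers)
        assert out["dist_kb"].iloc[0] == 52.5

    def test_same_position_distance_zero_local(self):
        markers = make_marker_map(["a", "b"], ["1", "1"], [500, 501])
        pairs = pd.DataFrame({"snp1": ["a"], "snp2": ["b"],
                              "p_full": [1e-7], "p_screen": [1e-7]})
        out = classify_pairs(pairs, self._thresholds(), [], markers)
        assert out["dist_kb"].iloc[0] == 0.0
        assert "local" in out["category"].iloc[0]

    def test_one_mb_boundary_inclusive_then_exclusive(self):
        t = self._thresholds()
        for delta, is_local in [(1_000_000, True), (1_000_001, False)]:
            markers = make_marker_map(["a", "b"], ["1", "1"], [100, 100 + delta])
            pairs = pd.DataFrame({"snp1": ["a"], "snp2": ["b"],
                                  "p_full": [1e-6], "p_screen": [1e-6]})
            out = classify_pairs(pairs, t, [], markers)
            assert ("local" in out["category"].iloc[0]) is is_local

    def test_cross_chromosome_distance_absent(self):
        markers = make_marker_map(["a", "b"], ["1", "2"], [100, 200])
        pairs = pd.DataFrame({"snp1": ["a"], "snp2": ["b"],
                              "p_full": [1e-20], "p_screen": [1e-20]})
        out = classify_pairs(pairs, self._thresholds(), [], markers)
        assert np.isnan(out["dist_kb"].iloc[0])
        assert "genomewide" in out["category"].iloc[0]
        assert "local" not in out["category"].iloc[0]

    def test_marginal_pair_requires_marginal_snp(self):
        markers = make_marker_map(["a", "b"], ["1", "1"], [100, 200])
        pairs = pd.DataFrame({"snp1": ["a"], "snp2": ["b"],
                              "p_full": [1e-11], "p_screen": [1e-11]})
        t = self._thresholds()
        with_flag = classify_pairs(pairs, t, ["a"], markers)
        without = classify_pairs(pairs, t, [], markers)
        assert "marginal_pair" in with_flag["category"].iloc[0]
        assert "marginal_pair" not in without["category"].iloc[0]

    def test_pairs_emitted_with_ordered_ids_deterministically(self, planted_cohort):
        g, y, _, _ = planted_cohort
        sub = g.subset(snp_mask=np.arange(g.n_snps) < 40)
        res1 = scan_pairs(sub, y, window="all", emit_p=1e-3)
        res2 = scan_pairs(sub, y, window="all", emit_p=1e-3)
        assert res1.drop(columns="category").equals(res2.drop(columns="category"))
        assert (res1["snp1"] <= res1["snp2"]).all()


def test_round_half_up_matches_table_convention():
    assert round_half_up(52.539, 1) == 52.5
    assert round_half_up(126.078, 1) == 126.1
    assert round_half_up(16.951, 1) == 17.0
    assert round_half_up(0.25, 1) == 0.3   # half goes up
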
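"""Diversity statistics, Weir–Cockerham theta, PCA, LD and LD-based Ne."""

import numpy as np
import pandas as pd
import pytest

from pairscan import popgen_stats as ps
from pairscan import synthetic_data as synth
from pairscan.containers import MISSING, GenotypeMatrix


class TestHeterozygosityStats:
    def test_all_heterozygotes(self):
        gm = GenotypeMatrix([f"s{i}" for i in range(10)], ["L"],
                            np.ones((10, 1), dtype=np.int8))
        stats = ps.heterozygosity_stats(gm, np.array(["g"] * 10))
        row = stats.per_locus.iloc[0]
        assert row["Ho"] == 1.0
        assert row["He"] == pytest.approx(0.5 * 20 / 19)
        assert row["F"] == pytest.approx(1 - 1 / (0.5 * 20 / 19))

    def test_monomorphic_group(self):
        gm = GenotypeMatrix(["a", "b", "c"], ["L"],
                            np.zeros((3, 1), dtype=np.int8))
        stats = ps.heterozygosity_stats(gm, np.array(["g"] * 3))
        row = stats.per_locus.iloc[0]
        assert row["Ho"] == 0.0 and row["He"] == 0.0
        assert np.isnan(row["F"])

    def test_mean_f_near_zero_under_hwe(self):
        gm, st, _ = synth.simulate_pair(synth.PairScenario(
            n_anadromous=60, n_resident=60, n_loci=2000, fst_target=0.0,
            seed=6, pair_label="f"))
        stats = ps.heterozygosity_stats(gm, np.array(["g"] * gm.n_samples))
        assert abs(stats.summary.iloc[0]["F_mean"]) < 0.02


class TestWcTheta:
    def test_alternate_fixation_gives_one(self):
        codes = np.vstack([np.zeros((30, 1)), np.full((30, 1), 2)]).astype(np.int8)
        gm = GenotypeMatrix([f"s{i}" for i in range(60)], ["L"], codes)
        groups = np.array(["A"] * 30 + ["B"] * 30)
        comp = ps.wc_theta_locus(gm, groups)
        assert comp["theta"].iloc[0] == pytest.approx(1.0)

    def test_identical_counts_match_hand_computation(self):
        """12 AA / 26 Aa / 12 aa in both groups: frozen plug-in values."""
        block = np.array([0] * 12 + [1] * 26 + [2] * 12, dtype=np.int8)
        codes = np.concatenate([block, block])[:, None]
        gm = GenotypeMatrix([f"s{i}" for i in range(100)], ["L"], codes)
        comp = ps.wc_theta_locus(gm, np.array(["A"] * 50 + ["B"] * 50))
        assert comp["a"].iloc[0] == pytest.approx(-0.0024489795918, abs=1e-10)
        assert comp["b"].iloc[0] == pytest.approx(-0.0075510204082, abs=1e-10)
        assert comp["c"].iloc[0] == pytest.approx(0.26, abs=1e-12)
        assert comp["theta"].iloc[0] == pytest.approx(-0.0097959183673, abs=1e-10)

    def test_expectation_zero_for_identical_frequencies(self):
        gm, st, _ = synth.simulate_pair(synth.PairScenario(
            n_anadromous=50, n_resident=50, n_loci=1000, fst_target=0.0,
            seed=17, pair_label="z"))
        comp = ps.wc_theta_locus(gm, st.population_of(gm.sample_ids))
        assert abs(comp["theta"].mean()) < 0.01

    def test_invariance_locus_order_and_sample_duplication(self):
        gm, st, _ = synth.simulate_pair(synth.PairScenario(
            n_anadromous=20, n_resident=20, n_loci=200, fst_target=0.09,
            seed=8, pair_label="inv"))
        groups = st.population_of(gm.sample_ids)
        base = ps.multilocus_theta(ps.wc_theta_locus(gm, groups))
        perm = np.random.default_rng(0).permutation(gm.n_loci)
        shuffled = gm.take_loci(perm)
        assert ps.multilocus_theta(ps.wc_theta_locus(shuffled, groups)) == \
            pytest.approx(base, abs=1e-12)
        doubled = GenotypeMatrix(
            gm.sample_ids + [s + "_dup" for s in gm.sample_ids],
            gm.locus_ids, np.vstack([gm.codes, gm.codes]))
        assert ps.multilocus_theta(
            ps.wc_theta_locus(doubled, np.concatenate([groups, groups]))
        ) == pytest.approx(base, abs=0.02)


class TestFstWithCi:
    def test_panmictic_ci_covers_zero(self):
        covered = 0
        for seed in range(5):
            gm, st, _ = synth.simulate_pair(synth.PairScenario(
                n_anadromous=50, n_resident=50, n_loci=800, fst_target=0.0,
                seed=seed, pair_label="c"))
            res = ps.fst_with_ci(gm, st.population_of(gm.sample_ids),
                                 reps=300, seed=seed)
            covered += res.ci_low <= 0 <= res.ci_high
        assert covered >= 4

    def test_ci_width_small_at_scale(self):
        gm, st, _ = synth.simulate_pair(synth.redfish_like(
            seed=1, n_outlier_loci=0))
        res = ps.fst_with_ci(gm, st.population_of(gm.sample_ids),
                             reps=1000, seed=1)
        assert res.ci_high - res.ci_low < 0.02
        assert res.ci_low <= res.theta <= res.ci_high

    def test_too_few_informative_loci(self):
        gm = GenotypeMatrix(["a", "b"], ["L"], np.array([[0], [0]], dtype=np.int8))
        with pytest.raises(ValueError):
            ps.fst_with_ci(gm, np.array(["A", "B"]), reps=10, seed=1)


class TestPca:
    def test_divergent_pair_separates_on_pc1(self):
        gm, st, _ = synth.simulate_pair(synth.redfish_like(seed=1, n_outlier_loci=0))
        pca = ps.pca_genotypes(gm)
        lab = st.population_of(gm.sample_ids) == "Redfish-Anadromous"
        s_a, s_r = pca.scores[lab, 0], pca.scores[~lab, 0]
        assert s_a.min() > s_r.max() or s_r.min() > s_a.max()

    def test_panmictic_pair_no_label_signal(self):
        gm, st, _ = synth.simulate_pair(synth.alturas_like(
            seed=2, n_causal_loci=0, n_anadromous=30, n_resident=30))
        pca = ps.pca_genotypes(gm)
        lab = (st.population_of(gm.sample_ids) == "Alturas-Anadromous").astype(float)
        r = max(abs(np.corrcoef(pca.scores[:, k], lab)[0, 1]) for k in range(3))
        assert r < 0.3

    def test_duplicate_samples_identical_scores(self, tiny_matrix):
        gm = GenotypeMatrix(
            tiny_matrix.sample_ids + [s + "b" for s in tiny_matrix.sample_ids],
            tiny_matrix.locus_ids, np.vstack([tiny_matrix.codes, tiny_matrix.codes]))
        pca = ps.pca_genotypes(gm)
        assert np.allclose(pca.scores[:4], pca.scores[4:], atol=1e-9)

    def test_constant_matrix_rejected(self):
        gm = GenotypeMatrix(["a", "b", "c"], ["L1", "L2"],
                            np.ones((3, 2), dtype=np.int8))
        with pytest.raises(ValueError):
            ps.pca_genotypes(gm)

    def test_explained_fractions_sum_le_one(self):
        gm, _, _ = synth.simulate_pair(synth.PairScenario(
            n_anadromous=10, n_resident=10, n_loci=50, fst_target=0.05,
            seed=4, pair_label="p"))
        pca = ps.pca_genotypes(gm)
        assert pca.explained_fraction.sum() <= 1.0 + 1e-9


class TestLd:
    def test_locus_with_itself(self, tiny_matrix):
        assert ps.ld_r2(tiny_matrix, "L0", "L0") == pytest.approx(1.0)

    def test_duplicated_column(self):
        col = np.array([0, 1, 2, 1, 0, 2, 1, 0], dtype=np.int8)
        gm = GenotypeMatrix([f"s{i}" for i in range(8)], ["a", "b"],
                            np.column_stack([col, col]))
        assert ps.ld_r2(gm, "a", "b") == pytest.approx(1.0)

    def test_constant_locus_undefined(self):
        gm = GenotypeMatrix(["a", "b", "c"], ["x", "y"],
                            np.array([[0, 1], [0, 2], [0, 0]], dtype=np.int8))
        assert np.isnan(ps.ld_r2(gm, "x", "y"))

    def test_independent_loci_mean_near_one_over_n(self):
        gm, _, _ = synth.simulate_pair(synth.PairScenario(
            n_anadromous=100, n_resident=100, n_loci=200, fst_target=0.0,
            seed=2, pair_label="ld"))
        R = ps.ld_r2_matrix(gm)
        m = np.nanmean(R[np.triu_indices(gm.n_loci, 1)])
        assert 0.5 / 200 < m < 1.5 / 200


class TestNeLd:
    def test_small_sample_branch_flagged(self):
        gm = synth.simulate_wright_fisher(50, 120, 6, 20, seed=3)
        est = ps.ne_ld_estimate(gm)
        assert est.small_sample_branch
        assert est.s_harmonic < 30

    def test_large_sample_branch(self):
        gm = synth.simulate_wright_fisher(100, 120, 6, 50, seed=3)
        est = ps.ne_ld_estimate(gm)
        assert not est.small_sample_branch
        assert est.n_pairs > 1000

    def test_nonpositive_drift_r2_reports_infinite(self):
        gm = synth.simulate_wright_fisher(10**6, 150, 2, 60, seed=7)
        est = ps.ne_ld_estimate(gm)
        assert est.ne == float("inf")
        assert est.ci_high == float("inf")
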
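"""Imputation, kinship, mixed-model association and residualization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pairscan import gwas_mlm as gw
from pairscan import synthetic_data as synth
from pairscan.containers import MISSING, GenotypeMatrix, RunConfig


class TestImputation:
    def test_complete_matrix_is_identity(self, tiny_matrix):
        gm = GenotypeMatrix(tiny_matrix.sample_ids, tiny_matrix.locus_ids,
                            np.abs(tiny_matrix.codes))
        out = gw.impute_genotypes(gm, np.array(["A"] * 4), seed=1)
        assert np.array_equal(out.codes, gm.codes)

    def test_fixed_locus_imputes_to_two(self):
        codes = np.full((6, 1), 2, dtype=np.int8)
        codes[0, 0] = MISSING
        gm = GenotypeMatrix([f"s{i}" for i in range(6)], ["L"], codes)
        out = gw.impute_genotypes(gm, np.array(["A"] * 6), seed=1)
        assert out.codes[0, 0] == 2

    def test_beats_random_guessing_on_masked_entries(self):
        gm, st, _ = synth.simulate_pair(synth.redfish_like(
            seed=7, n_loci=400, n_outlier_loci=0))
        masked = synth.inject_missingness(gm, 0.3, seed=7)
        pops = st.population_of(gm.sample_ids)
        imp = gw.impute_genotypes(masked, pops, seed=7)
        holes = masked.codes == MISSING
        err = (imp.codes[holes] != gm.codes[holes]).mean()
        counts = np.bincount(gm.codes.ravel(), minlength=3) / gm.codes.size
        random_err = 1.0 - (counts**2).sum()
        assert err < random_err


class TestKinship:
    def test_zero_centered_matrix_gives_zero(self):
        gm = GenotypeMatrix([f"s{i}" for i in range(5)], ["L1", "L2"],
                            np.ones((5, 2), dtype=np.int8))
        # all heterozygous at p=0.5: Z = 0 but loci are polymorphic
        K = gw.vanraden_kinship(gm)
        assert np.allclose(K, 0.0)

    def test_homozygous_individual_diagonal_two(self):
        rng = np.random.default_rng(0)
        m = 400
        codes = rng.integers(0, 3, (20, m)).astype(np.int8)
        # force p-hat = 0.5 per locus by mirroring samples
        codes = np.vstack([codes, 2 - codes])
        codes[0, :] = np.where(rng.random(m) < 0.5, 0, 2)
        codes[20, :] = 2 - codes[0, :]
        gm = GenotypeMatrix([f"s{i}" for i in range(40)],
                            [f"L{j}" for j in range(m)], codes)
        K = gw.vanraden_kinship(gm)
        assert K[0, 0] == pytest.approx(2.0, abs=0.05)

    def test_clone_off_diagonal_matches_diagonal(self, tiny_matrix):
        codes = np.abs(tiny_matrix.codes)
        gm = GenotypeMatrix(["a", "b", "a2"], tiny_matrix.locus_ids,
                            np.vstack([codes[0], codes[1], codes[0]]))
        K = gw.vanraden_kinship(gm)
        assert K[0, 2] == pytest.approx(K[0, 0], abs=1e-12)

    def test_missing_or_monomorphic_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            gw.vanraden_kinship(tiny_matrix)  # has a missing cell
        gm = GenotypeMatrix(["a", "b"], ["L1", "L2"],
                            np.zeros((2, 2), dtype=np.int8))
        with pytest.raises(ValueError):
            gw.vanraden_kinship(gm)


class TestCovariateSelection:
    def test_candidate_identical_to_phenotype_always_selected(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 80).astype(float)
        cands = {"sex": rng.random(80), "PC1": y.copy()}
        chosen = gw.select_covariates(y, cands, np.eye(80), order=["sex", "PC1"])
        assert "PC1" in chosen

    def test_divergent_pair_selects_structure_axis(self):
        gm, st, _ = synth.simulate_pair(synth.redfish_like(
            seed=1, n_loci=800, n_outlier_loci=0))
        fit = gw.run_gwas(gm, st, RunConfig(seed=1))
        assert any(c.startswith("PC") for c in fit.fixed_effects)

    def test_panmictic_pair_selects_at_most_sex(self):
        gm, st, _ = synth.simulate_pair(synth.alturas_like(seed=3))
        fit = gw.run_gwas(gm, st, RunConfig(seed=3))
        assert set(fit.fixed_effects) <= {"sex"}


class TestMarkerTests:
    def test_marker_identical_to_phenotype_is_top_hit(self):
        rng = np.random.default_rng(1)
        n = 80
        y = rng.integers(0, 2, n).astype(float)
        codes = rng.integers(0, 3, (n, 60)).astype(np.int8)
        codes[:, 7] = (2 * y).astype(np.int8)
        gm = GenotypeMatrix([f"s{i}" for i in range(n)],
                            [f"L{j}" for j in range(60)], codes)
        fit = gw.fit_mlm_marker_tests(y, gm, {}, gw.vanraden_kinship(gm))
        tab = fit.marker_table
        assert tab.loc[tab["p"].idxmin(), "locus"] == "L7"
        assert bool(tab.loc[7, "significant"])

    def test_permuted_phenotype_pvalues_uniform(self):
        gm, st, _ = synth.simulate_pair(synth.redfish_like(
            seed=5, n_loci=2000, n_outlier_loci=0))
        pops = st.population_of(gm.sample_ids)
        gmi = gw.impute_genotypes(gm, pops, seed=1)
        K = gw.vanraden_kinship(gmi)
        y = np.random.default_rng(3).permutation(
            st.life_history_of(gm.sample_ids))
        fit = gw.fit_mlm_marker_tests(y, gmi, {}, K)
        assert stats.kstest(fit.marker_table["p"], "uniform").statistic < 0.05

    def test_reml_optimum_reproducible(self):
        gm, st, _ = synth.simulate_pair(synth.redfish_like(
            seed=2, n_loci=300, n_outlier_loci=0))
        y = st.life_history_of(gm.sample_ids)
        gmi = gw.impute_genotypes(gm, st.population_of(gm.sample_ids), seed=1)
        K = gw.vanraden_kinship(gmi)
        fits = [gw.fit_mlm_marker_tests(y, gmi, {}, K) for _ in range(2)]
        assert fits[0].lam == pytest.approx(fits[1].lam, abs=1e-6)
        assert fits[0].loglik_reml == pytest.approx(fits[1].loglik_reml, abs=1e-6)


class TestResidualize:
    def test_zero_kinship_no_covariates_centers_phenotype(self):
        rng = np.random.default_rng(2)
        n = 30
        y = rng.integers(0, 2, n).astype(float)
        codes = rng.integers(0, 3, (n, 5)).astype(np.int8)
        gm = GenotypeMatrix([f"s{i}" for i in range(n)],
                            [f"L{j}" for j in range(5)], codes)
        res = gw.residualize(y, gm, {}, np.zeros((n, n)))
        assert np.allclose(res.phenotype, y - y.mean(), atol=1e-8)

    def test_residual_orthogonal_to_fixed_effects(self):
        gm, st, _ = synth.simulate_pair(synth.redfish_like(
            seed=5, n_loci=300, n_outlier_loci=0))
        fit = gw.run_gwas(gm, st, RunConfig(seed=5))
        res = gw.residualize_fit(fit)
        for i, name in enumerate(fit.fixed_effects):
            r = np.corrcoef(res.phenotype, fit._X[:, i + 1])[0, 1]
            assert abs(r) < 0.05, name

    def test_clones_get_equal_residuals(self):
        rng = np.random.default_rng(4)
        n = 20
        codes = rng.integers(0, 3, (n, 50)).astype(np.int8)
        codes[1] = codes[0]
        gm = GenotypeMatrix([f"s{i}" for i in range(n)],
                            [f"L{j}" for j in range(50)], codes)
        y = rng.integers(0, 2, n).astype(float)
        y[1] = y[0]
        res = gw.residualize(y, gm, {}, gw.vanraden_kinship(gm))
        assert res.phenotype[0] == pytest.approx(res.phenotype[1], abs=1e-8)


def test_genomic_inflation_identity_on_uniform():
    p = np.linspace(1e-4, 1, 20001)[:-1]
    assert gw.genomic_inflation(p) == pytest.approx(1.0, abs=0.01)
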
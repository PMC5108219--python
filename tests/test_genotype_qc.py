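"""Locus/individual filters, HWE exact test and the BY-FDR threshold."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from pairscan import genotype_qc as qc
from pairscan import synthetic_data as synth
from pairscan.containers import MISSING, GenotypeMatrix, RunConfig, SampleTable


def hwe_oracle(n_aa: int, n_het: int, n_bb: int) -> Fraction:
    """Exact-rational enumeration of the Levene conditional distribution.

    Independent of the implementation under test: uses binomial coefficients
    and Fraction arithmetic throughout.
    """
    n = n_aa + n_het + n_bb
    n_a = 2 * n_aa + n_het
    n_b = 2 * n_bb + n_het
    n_minor = min(n_a, n_b)

    def prob(h: int) -> Fraction:
        aa = (n_a - h) // 2
        bb = (n_b - h) // 2
        num = Fraction(
            comb(n, h) * comb(n - h, aa) * 2**h,
            comb(2 * n, n_a),
        )
        # multinomial n!/(aa! h! bb!) = C(n,h)*C(n-h,aa); divide by C(2n, n_a)
        return num

    feasible = list(range(n_minor % 2, n_minor + 1, 2))
    probs = {h: prob(h) for h in feasible}
    p_obs = probs[n_het]
    return sum(p for p in probs.values() if p <= p_obs)


class TestHweExactTest:
    @pytest.mark.parametrize("counts,expected", [
        ((2, 0, 2), 6 / 70),        # enumerated by hand: h in {0,2,4}
        ((1, 2, 1), 1.0),           # observed h is modal -> everything summed
        ((5, 0, 0), 1.0),           # monomorphic: single feasible configuration
    ])
    def test_known_configurations(self, counts, expected):
        assert qc.hwe_exact_test(*counts) == pytest.approx(expected, abs=1e-12)

    def test_matches_rational_oracle_small_n(self):
        for n in range(1, 13):
            for n_aa in range(n + 1):
                for n_het in range(n - n_aa + 1):
                    n_bb = n - n_aa - n_het
                    got = qc.hwe_exact_test(n_aa, n_het, n_bb)
                    want = float(hwe_oracle(n_aa, n_het, n_bb))
                    assert got == pytest.approx(want, abs=1e-12), (n_aa, n_het, n_bb)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            qc.hwe_exact_test(-1, 2, 3)

    def test_rejection_rate_near_nominal_under_hwe(self):
        """Under HWE-true simulation, raw alpha=0.05 rejects 3-7% of loci."""
        gm, st, _ = synth.simulate_pair(synth.PairScenario(
            n_anadromous=100, n_resident=2, n_loci=2000, fst_target=0.0,
            seed=13, pair_label="h"))
        sub = gm.codes[:100]
        rej = 0
        tested = 0
        for j in range(gm.n_loci):
            col = sub[:, j]
            p = qc.hwe_exact_test(int((col == 2).sum()), int((col == 1).sum()),
                                  int((col == 0).sum()))
            tested += 1
            rej += p < 0.05
        assert 0.03 <= rej / tested <= 0.07


class TestByFdrThreshold:
    def test_single_test_equals_q(self):
        assert qc.by_fdr_threshold(1, 0.05) == pytest.approx(0.05)

    def test_hand_computed_m4(self):
        # harmonic sum 1 + 1/2 + 1/3 + 1/4 = 25/12
        assert qc.by_fdr_threshold(4, 0.05) == pytest.approx(0.05 / (25 / 12))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            qc.by_fdr_threshold(0, 0.05)
        with pytest.raises(ValueError):
            qc.by_fdr_threshold(10, 1.5)


class TestMaf:
    def test_hand_counts(self):
        # {AA,AA,AA,Aa} coded as dosage of the minor allele: 0,0,0,1
        gm = GenotypeMatrix(list("abcd"), ["L"], np.array([[0], [0], [0], [1]]))
        assert qc.compute_maf(gm)[0] == pytest.approx(1 / 8)

    def test_all_heterozygotes(self):
        gm = GenotypeMatrix(list("ab"), ["L"], np.array([[1], [1]]))
        assert qc.compute_maf(gm)[0] == pytest.approx(0.5)

    def test_missing_excluded_from_denominator(self):
        gm = GenotypeMatrix(list("abcd"), ["L"],
                            np.array([[2], [2], [MISSING], [1]]))
        # p = 5/6 -> MAF 1/6
        assert qc.compute_maf(gm)[0] == pytest.approx(1 / 6)


class TestFilters:
    def test_individual_callrate_boundary(self):
        codes = np.zeros((2, 100), dtype=np.int8)
        codes[0, :26] = MISSING  # 74% called -> removed
        codes[1, :25] = MISSING  # 75% called -> retained
        gm = GenotypeMatrix(["low", "edge"], [f"L{j}" for j in range(100)], codes)
        out, rep = qc.filter_individuals(gm, 0.75)
        assert out.sample_ids == ["edge"]
        assert rep.removed_counts["individual_callrate"] == 1

    def test_no_missing_nothing_removed(self, tiny_matrix):
        gm = GenotypeMatrix(tiny_matrix.sample_ids, tiny_matrix.locus_ids,
                            np.abs(tiny_matrix.codes))
        out, rep = qc.filter_individuals(gm)
        assert out.n_samples == gm.n_samples

    def test_constructed_callrate_counts(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 3, (10, 40)).astype(np.int8)
        for i in range(3):
            codes[i, : 40 - int(0.7 * 40) + 10] = MISSING  # push below 75%
        gm = GenotypeMatrix([f"s{i}" for i in range(10)],
                            [f"L{j}" for j in range(40)], codes)
        out, rep = qc.filter_individuals(gm, 0.75)
        assert rep.removed_counts["individual_callrate"] == 3
        assert out.n_samples == 7

    def test_locus_filter_boundaries(self):
        # 50 samples; locus0 MAF=0.04 (removed), locus1 MAF=0.05 (kept),
        # locus2 85% het (removed), locus3 31% missing (removed)
        n = 50
        codes = np.zeros((n, 4), dtype=np.int8)
        codes[:4, 0] = 1               # MAF 4/100 = 0.04 -> removed
        codes[:5, 1] = 1               # MAF 5/100 = 0.05 -> boundary kept
        codes[:, 2] = 1                # 100% heterozygous -> removed as PSV
        codes[16:26, 3] = 1            # called: 34, het 10/34, MAF 10/68
        codes[:16, 3] = MISSING        # 16/50 = 32% missing -> removed
        gm = GenotypeMatrix([f"s{i}" for i in range(n)],
                            ["low_maf", "edge_maf", "psv", "gappy"], codes)
        out, rep = qc.filter_loci(gm, 0.05, 0.80, 0.30)
        assert "low_maf" in rep.removed_loci["maf"]
        assert "edge_maf" in out.locus_ids
        assert "psv" in rep.removed_loci["heterozygosity"]
        assert "gappy" in rep.removed_loci["missingness"]


class TestHweCrossPopulationFilter:
    def _matrix(self, n_pops=4, violate_in=3):
        """One locus all-het (HWE violation) in `violate_in` populations."""
        rng = np.random.default_rng(1)
        blocks = []
        pops = []
        for k in range(n_pops):
            codes = rng.binomial(2, 0.5, size=(30, 60)).astype(np.int8)
            if k < violate_in:
                codes[:, 0] = 1  # every individual heterozygous
            blocks.append(codes)
            pops += [f"P{k}"] * 30
        gm = GenotypeMatrix([f"s{i}" for i in range(30 * n_pops)],
                            [f"L{j}" for j in range(60)], np.vstack(blocks))
        return gm, np.array(pops)

    def test_violation_in_three_of_four_removed(self):
        gm, pops = self._matrix(violate_in=3)
        out, rep = qc.hwe_cross_population_filter(gm, pops)
        assert "L0" in rep.removed_loci["hwe"]

    def test_violation_in_two_retained(self):
        gm, pops = self._matrix(violate_in=2)
        out, rep = qc.hwe_cross_population_filter(gm, pops)
        assert "L0" in out.locus_ids

    def test_fewer_than_three_populations_noop(self):
        gm, pops = self._matrix(n_pops=2, violate_in=2)
        out, rep = qc.hwe_cross_population_filter(gm, pops)
        assert out.n_loci == gm.n_loci
        assert rep.removed_counts["hwe"] == 0


def test_filter_chain_idempotent():
    gm, st, _ = synth.simulate_two_lakes(
        synth.redfish_like(seed=3, n_loci=150, n_outlier_loci=0,
                           n_anadromous=20, n_resident=20, missing_rate=0.05),
        synth.alturas_like(seed=3, n_loci=150, n_anadromous=14, n_resident=20,
                           missing_rate=0.05),
        seed=3)
    cfg = RunConfig(seed=3)
    once, _ = qc.apply_filters(gm, st, cfg)
    twice, rep2 = qc.apply_filters(once, st.subset(once.sample_ids), cfg)
    assert twice.locus_ids == once.locus_ids
    assert twice.sample_ids == once.sample_ids
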
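"""Genotype quality control.

Filter chain (order matters and is logged): individual call rate, global MAF,
global observed heterozygosity (paralog screen), per-locus missingness, and a
cross-population Hardy–Weinberg filter. Boundary semantics follow the filter
definitions directionally: an individual is dropped when *fewer than* 75% of
loci are called; a locus is dropped when MAF is *less than* 0.05, observed
heterozygosity is *greater than* 80%, or *more than* 30% of individuals are
missing; the HWE filter removes loci out of equilibrium (at the BY-FDR level)
in three or more collections.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, RunConfig, SampleTable

logger = logging.getLogger("pairscan")

__all__ = [
    "FilterReport",
    "compute_maf",
    "compute_het_observed",
    "filter_individuals",
    "filter_loci",
    "hwe_exact_test",
    "by_fdr_threshold",
    "hwe_cross_population_filter",
    "apply_filters",
]


@dataclass
class FilterReport:
    """What each filter removed, in application order."""

    n_samples_in: int = 0
    n_loci_in: int = 0
    removed_counts: dict[str, int] = field(default_factory=dict)
    removed_samples: list[str] = field(default_factory=list)
    removed_loci: dict[str, list[str]] = field(default_factory=dict)
    surviving_samples: list[str] = field(default_factory=list)
    surviving_loci: list[str] = field(default_factory=list)
    hwe_pvalues: pd.DataFrame | None = None

    def merge(self, other: "FilterReport") -> "FilterReport":
        out = FilterReport(
            n_samples_in=self.n_samples_in or other.n_samples_in,
            n_loci_in=self.n_loci_in or other.n_loci_in,
        )
        out.removed_counts = {**self.removed_counts, **other.removed_counts}
        out.removed_samples = self.removed_samples + other.removed_samples
        out.removed_loci = {**self.removed_loci, **other.removed_loci}
        out.surviving_samples = other.surviving_samples or self.surviving_samples
        out.surviving_loci = other.surviving_loci or self.surviving_loci
        out.hwe_pvalues = other.hwe_pvalues if other.hwe_pvalues is not None else self.hwe_pvalues
        return out

    def to_tsv(self, path: str | Path) -> None:
        rows = [{"filter": k, "n_removed": v} for k, v in self.removed_counts.items()]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def compute_maf(gm: GenotypeMatrix) -> np.ndarray:
    """Global minor allele frequency per locus (NaN where all calls missing)."""
    p = gm.allele_freq()
    return np.minimum(p, 1.0 - p)


def compute_het_observed(gm: GenotypeMatrix) -> np.ndarray:
    """Global fraction of heterozygous calls among non-missing calls."""
    called = gm.codes != MISSING
    het = gm.codes == 1
    with np.errstate(invalid="ignore"):
        return np.where(called.sum(0) > 0, het.sum(0) / np.maximum(called.sum(0), 1),
                        np.nan)


def filter_individuals(gm: GenotypeMatrix, callrate_min: float = 0.75
                       ) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop individuals with call rate strictly below ``callrate_min``."""
    called = (gm.codes != MISSING).mean(axis=1)
    keep = called >= callrate_min
    report = FilterReport(n_samples_in=gm.n_samples, n_loci_in=gm.n_loci)
    report.removed_samples = [s for s, k in zip(gm.sample_ids, keep) if not k]
    report.removed_counts["individual_callrate"] = int((~keep).sum())
    out = gm.take_samples(np.flatnonzero(keep))
    report.surviving_samples = out.sample_ids
    report.surviving_loci = out.locus_ids
    return out, report


def filter_loci(gm: GenotypeMatrix, maf_min: float = 0.05, het_max: float = 0.80,
                missing_max: float = 0.30) -> tuple[GenotypeMatrix, FilterReport]:
    """Locus filters: MAF, excess heterozygosity, missingness (in that order)."""
    report = FilterReport(n_samples_in=gm.n_samples, n_loci_in=gm.n_loci)
    maf = compute_maf(gm)
    bad_maf = np.isnan(maf) | (maf < maf_min)
    report.removed_loci["maf"] = [l for l, b in zip(gm.locus_ids, bad_maf) if b]
    report.removed_counts["maf"] = int(bad_maf.sum())
    gm = gm.take_loci(np.flatnonzero(~bad_maf))

    het = compute_het_observed(gm)
    bad_het = het > het_max
    report.removed_loci["heterozygosity"] = [l for l, b in zip(gm.locus_ids, bad_het) if b]
    report.removed_counts["heterozygosity"] = int(bad_het.sum())
    gm = gm.take_loci(np.flatnonzero(~bad_het))

    miss = (gm.codes == MISSING).mean(axis=0)
    bad_miss = miss > missing_max
    report.removed_loci["missingness"] = [l for l, b in zip(gm.locus_ids, bad_miss) if b]
    report.removed_counts["missingness"] = int(bad_miss.sum())
    gm = gm.take_loci(np.flatnonzero(~bad_miss))

    report.surviving_samples = gm.sample_ids
    report.surviving_loci = gm.locus_ids
    return gm, report


def hwe_exact_test(n_aa_hom: int, n_het: int, n_bb_hom: int) -> float:
    """Two-sided Hardy–Weinberg exact test (Levene's conditional distribution).

    Enumerates every heterozygote count ``h`` compatible with the observed
    allele counts (same parity as the minor allele count) and returns the sum
    of conditional probabilities not exceeding that of the observed
    configuration — the standard probability-method exact p.
    """
    if min(n_aa_hom, n_het, n_bb_hom) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_hom + n_het + n_bb_hom
    if n < 1:
        raise ValueError("at least one genotype required")
    n_a = 2 * n_aa_hom + n_het
    n_b = 2 * n_bb_hom + n_het
    n_minor = min(n_a, n_b)

    # log P(h | n, n_a) up to a shared constant:
    #   P ∝ n! / (n_aa! h! n_bb!) * 2^h  with n_aa = (n_a - h)/2 etc.
    lgamma = math.lgamma

    def log_weight(h: int) -> float:
        aa = (n_a - h) // 2
        bb = (n_b - h) // 2
        return (h * math.log(2.0) - lgamma(aa + 1) - lgamma(h + 1) - lgamma(bb + 1))

    feasible = range(n_minor % 2, n_minor + 1, 2)
    logs = np.array([log_weight(h) for h in feasible])
    logs -= logs.max()
    weights = np.exp(logs)
    probs = weights / weights.sum()
    p_obs = probs[list(feasible).index(n_het)]
    # tolerance absorbs float noise when summing equal-probability tails
    return float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())


def by_fdr_threshold(m: int, q: float = 0.05) -> float:
    """Benjamini–Yekutieli per-test p-value threshold ``q / sum_{i<=m} 1/i``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    harmonic = np.sum(1.0 / np.arange(1, m + 1))
    return float(q / harmonic)


def _hwe_pvalues_per_population(gm: GenotypeMatrix, populations: np.ndarray
                                ) -> pd.DataFrame:
    """Exact HWE p per locus per population (NaN where untestable)."""
    pops = pd.unique(populations)
    out = pd.DataFrame(index=gm.locus_ids, columns=pops, dtype=float)
    for pop in pops:
        sub = gm.codes[populations == pop]
        for j, locus in enumerate(gm.locus_ids):
            col = sub[:, j]
            col = col[col != MISSING]
            if col.size == 0:
                continue
            n_bb = int((col == 0).sum())
            n_het = int((col == 1).sum())
            n_aa = int((col == 2).sum())
            out.loc[locus, pop] = hwe_exact_test(n_aa, n_het, n_bb)
    return out


def hwe_cross_population_filter(gm: GenotypeMatrix, populations: np.ndarray,
                                q: float = 0.05, min_violations: int = 3
                                ) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove loci out of HWE (BY-FDR within population) in >= 3 collections.

    With fewer than three population labels the filter is a warned no-op.
    """
    report = FilterReport(n_samples_in=gm.n_samples, n_loci_in=gm.n_loci)
    populations = np.asarray(populations)
    n_pops = len(pd.unique(populations))
    pvals = _hwe_pvalues_per_population(gm, populations)
    report.hwe_pvalues = pvals
    if n_pops < min_violations:
        logger.warning("HWE cross-population filter skipped: only %d populations",
                       n_pops)
        report.removed_counts["hwe"] = 0
        report.surviving_samples = gm.sample_ids
        report.surviving_loci = gm.locus_ids
        return gm, report
    violations = pd.DataFrame(False, index=pvals.index, columns=pvals.columns)
    for pop in pvals.columns:
        tested = pvals[pop].notna()
        thr = by_fdr_threshold(int(tested.sum()), q) if tested.any() else 0.0
        violations[pop] = (pvals[pop] < thr) & tested
    bad = violations.sum(axis=1) >= min_violations
    report.removed_loci["hwe"] = list(pvals.index[bad])
    report.removed_counts["hwe"] = int(bad.sum())
    keep = [j for j, l in enumerate(gm.locus_ids) if not bad[l]]
    out = gm.take_loci(keep)
    report.surviving_samples = out.sample_ids
    report.surviving_loci = out.locus_ids
    return out, report


def apply_filters(gm: GenotypeMatrix, st: SampleTable, config: RunConfig
                  ) -> tuple[GenotypeMatrix, FilterReport]:
    """Full QC chain: individuals -> MAF -> heterozygosity -> missingness -> HWE."""
    gm1, rep1 = filter_individuals(gm, config.indiv_callrate_min)
    gm2, rep2 = filter_loci(gm1, config.maf_min, config.het_max,
                            config.locus_missing_max)
    pops = st.population_of(gm2.sample_ids)
    gm3, rep3 = hwe_cross_population_filter(gm2, pops, q=config.fdr_q)
    report = rep1.merge(rep2).merge(rep3)
    report.n_samples_in = gm.n_samples
    report.n_loci_in = gm.n_loci
    logger.info("QC: %d/%d samples, %d/%d loci retained; removals %s",
                gm3.n_samples, gm.n_samples, gm3.n_loci, gm.n_loci,
                report.removed_counts)
    return gm3, report
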
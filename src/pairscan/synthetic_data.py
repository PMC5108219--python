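"""Synthetic genotype/phenotype generators.

The generative model is the Balding–Nichols F-model: per locus an ancestral
frequency ``p̄ ~ Uniform(0.05, 0.95)`` is drawn, each population's frequency is
Beta-distributed around it with variance ``c·p̄(1−p̄)`` (``c`` playing the role
of F_ST), and genotypes are binomial (Hardy–Weinberg within population).
Divergent-selection loci are planted by elevating ``c`` at a subset of loci;
causal loci for the binary life history act on a standard-normal liability.

Two ready-made scenarios mirror the study system: a strongly differentiated
pair (``redfish_like``, F_ST ≈ 0.09, n = 103 + 45) and a panmictic pair
(``alturas_like``, F_ST ≈ 0, n = 14 + 49) at ~2,600 biallelic loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, SampleTable, substream_rng

__all__ = [
    "PairScenario",
    "SimTruth",
    "simulate_pair",
    "simulate_two_lakes",
    "inject_missingness",
    "simulate_wright_fisher",
    "redfish_like",
    "alturas_like",
]


@dataclass
class PairScenario:
    """Parameters for one resident/anadromous population pair."""

    n_anadromous: int = 50
    n_resident: int = 50
    n_loci: int = 2600
    fst_target: float = 0.09
    n_outlier_loci: int = 0
    outlier_fst: float = 0.4
    n_causal_loci: int = 0
    effect_size: float = 0.8
    missing_rate: float = 0.0
    seed: int = 1
    pair_label: str = "pair"

    def __post_init__(self) -> None:
        if self.n_anadromous < 2 or self.n_resident < 2:
            raise ValueError("each collection needs at least 2 individuals")
        if not (0.0 <= self.fst_target < 1.0):
            raise ValueError("fst_target must be in [0, 1)")
        if self.n_outlier_loci > 0 and self.outlier_fst <= self.fst_target:
            raise ValueError("outlier_fst must exceed fst_target for planted outliers")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_outlier_loci + self.n_causal_loci > self.n_loci:
            raise ValueError("more planted loci than loci")


@dataclass
class SimTruth:
    """Ground truth of a simulation run, for recovery benchmarks."""

    outlier_locus_ids: set[str]
    causal_locus_ids: set[str]
    ancestral_freq: pd.Series
    pop_freq: pd.DataFrame
    causal_effects: dict[str, float] = field(default_factory=dict)


def redfish_like(**overrides) -> PairScenario:
    """Strongly differentiated pair: F_ST ≈ 0.09, 103 anadromous + 45 resident."""
    kw = dict(
        n_anadromous=103, n_resident=45, n_loci=2600, fst_target=0.09,
        n_outlier_loci=130, outlier_fst=0.4, n_causal_loci=0,
        pair_label="Redfish",
    )
    kw.update(overrides)
    return PairScenario(**kw)


def alturas_like(**overrides) -> PairScenario:
    """Panmictic pair: F_ST ≈ 0, 14 anadromous + 49 resident, liability trait."""
    kw = dict(
        n_anadromous=14, n_resident=49, n_loci=2600, fst_target=0.0,
        n_outlier_loci=0, n_causal_loci=5, effect_size=0.8,
        pair_label="Alturas",
    )
    kw.update(overrides)
    return PairScenario(**kw)


def _bn_population_freq(rng: np.random.Generator, p_anc: np.ndarray,
                        c: np.ndarray) -> np.ndarray:
    """Draw one population's frequencies from the Balding–Nichols Beta.

    ``c`` is the divergence parameter per locus; c = 0 degenerates to the
    shared ancestral frequency.
    """
    p = np.asarray(p_anc, dtype=float)
    c = np.broadcast_to(np.asarray(c, dtype=float), p.shape).copy()
    out = p.copy()
    pos = c > 0
    if pos.any():
        scale = (1.0 - c[pos]) / c[pos]
        out[pos] = rng.beta(p[pos] * scale, (1.0 - p[pos]) * scale)
    return out


def simulate_pair(scenario: PairScenario) -> tuple[GenotypeMatrix, SampleTable, SimTruth]:
    """Simulate one population pair under the F-model.

    For a divergent pair (``fst_target > 0``) the binary life history equals
    the population label, as in a system where ecotype and population
    coincide. For a panmictic pair the phenotype is liability-based: causal
    dosages shift a standard-normal liability and the top ``n_anadromous``
    liabilities are scored anadromous, so planted causal loci are detectable
    by association.
    """
    sc = scenario
    if sc.fst_target == 0.0 and sc.n_outlier_loci > 0 and sc.outlier_fst == 0.0:
        raise ValueError("panmictic scenario cannot plant outliers with outlier_fst=0")
    rng = substream_rng(sc.seed, f"simulate_pair:{sc.pair_label}:ancestral")
    p_anc = rng.uniform(0.05, 0.95, size=sc.n_loci)
    return _simulate_pair_at(sc, p_anc, sc.seed)


def simulate_two_lakes(
    redfish: PairScenario | None = None,
    alturas: PairScenario | None = None,
    between_lake_fst: float = 0.05,
    seed: int = 1,
) -> tuple[GenotypeMatrix, SampleTable, dict[str, SimTruth]]:
    """Simulate the four-collection design: two lake systems, shared loci.

    A lake-level frequency is drawn around the global ancestral frequency with
    divergence ``between_lake_fst``; each pair then diverges within its lake
    per its own scenario. Locus identifiers are shared across all four
    collections, as for a common SNP panel.
    """
    redfish = redfish or redfish_like(seed=seed)
    alturas = alturas or alturas_like(seed=seed)
    if redfish.n_loci != alturas.n_loci:
        raise ValueError("both lakes must share one locus panel")
    rng = substream_rng(seed, "simulate_two_lakes")
    n_loci = redfish.n_loci
    p_global = rng.uniform(0.05, 0.95, size=n_loci)
    truths: dict[str, SimTruth] = {}
    parts: list[tuple[GenotypeMatrix, SampleTable]] = []
    for sc in (redfish, alturas):
        p_lake = _bn_population_freq(rng, p_global, between_lake_fst)
        p_lake = np.clip(p_lake, 0.02, 0.98)
        gm, st, truth = _simulate_pair_at(sc, p_lake, seed)
        truths[sc.pair_label] = truth
        parts.append((gm, st))
    gm_all = GenotypeMatrix(
        parts[0][0].sample_ids + parts[1][0].sample_ids,
        parts[0][0].locus_ids,
        np.vstack([parts[0][0].codes, parts[1][0].codes]),
    )
    st_all = SampleTable(pd.concat([parts[0][1].table, parts[1][1].table],
                                   ignore_index=True))
    return gm_all, st_all, truths


def _simulate_pair_at(scenario: PairScenario, p_anc: np.ndarray,
                      master_seed: int) -> tuple[GenotypeMatrix, SampleTable, SimTruth]:
    """simulate_pair with an externally supplied ancestral frequency vector."""
    sc = scenario
    rng = substream_rng(master_seed, f"simulate_pair_at:{sc.pair_label}")
    locus_ids = [f"L{j:05d}" for j in range(sc.n_loci)]
    # plant outliers anywhere; causal loci only where MAF can be decent
    order = rng.permutation(sc.n_loci)
    outlier_idx = np.sort(order[: sc.n_outlier_loci])
    remaining = order[sc.n_outlier_loci:]
    informative = remaining[(p_anc[remaining] >= 0.2) & (p_anc[remaining] <= 0.8)]
    if len(informative) < sc.n_causal_loci:
        raise ValueError("not enough intermediate-frequency loci for causal set")
    causal_idx = np.sort(informative[: sc.n_causal_loci])
    c = np.full(sc.n_loci, sc.fst_target)
    c[outlier_idx] = sc.outlier_fst
    freq_a = _bn_population_freq(rng, p_anc, c)
    freq_r = _bn_population_freq(rng, p_anc, c)
    n_a, n_r = sc.n_anadromous, sc.n_resident
    codes = np.vstack([
        rng.binomial(2, freq_a[None, :], size=(n_a, sc.n_loci)),
        rng.binomial(2, freq_r[None, :], size=(n_r, sc.n_loci)),
    ]).astype(np.int8)
    sample_ids = [f"{sc.pair_label}_A{i:03d}" for i in range(n_a)] + [
        f"{sc.pair_label}_R{i:03d}" for i in range(n_r)]
    populations = [f"{sc.pair_label}-Anadromous"] * n_a + [
        f"{sc.pair_label}-Resident"] * n_r
    causal_effects: dict[str, float] = {}
    if sc.fst_target > 0:
        life_history = np.array([1] * n_a + [0] * n_r, dtype=float)
    else:
        liability = rng.standard_normal(n_a + n_r)
        for j in causal_idx:
            dose = codes[:, j].astype(float)
            liability += sc.effect_size * (dose - dose.mean())
            causal_effects[locus_ids[j]] = sc.effect_size
        cut = np.sort(liability)[-(n_a)]
        life_history = (liability >= cut).astype(float)
    sex = np.where(rng.random(n_a + n_r) < 0.5, "M", "F")
    gm = GenotypeMatrix(sample_ids, locus_ids, codes)
    if sc.missing_rate > 0:
        gm = inject_missingness(gm, sc.missing_rate, seed=master_seed)
    st = SampleTable(pd.DataFrame({
        "sample_id": sample_ids, "population": populations,
        "life_history": life_history, "sex": sex}))
    truth = SimTruth(
        outlier_locus_ids={locus_ids[j] for j in outlier_idx},
        causal_locus_ids={locus_ids[j] for j in causal_idx},
        ancestral_freq=pd.Series(p_anc, index=locus_ids),
        pop_freq=pd.DataFrame({populations[0]: freq_a, populations[-1]: freq_r},
                              index=locus_ids),
        causal_effects=causal_effects,
    )
    return gm, st, truth


def inject_missingness(gm: GenotypeMatrix, rate: float, seed: int) -> GenotypeMatrix:
    """Set each cell missing independently with probability ``rate``."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must be in [0, 1)")
    if rate == 0.0:
        return GenotypeMatrix(list(gm.sample_ids), list(gm.locus_ids), gm.codes.copy())
    rng = substream_rng(seed, "inject_missingness")
    mask = rng.random(gm.codes.shape) < rate
    codes = gm.codes.copy()
    codes[mask] = MISSING
    return GenotypeMatrix(list(gm.sample_ids), list(gm.locus_ids), codes)


_LARGE_NE_CUTOFF = 100_000


def simulate_wright_fisher(ne: int, n_loci: int, n_generations: int,
                           sample_size: int, seed: int) -> GenotypeMatrix:
    """Individual-based Wright–Fisher drift at unlinked loci, then sampling.

    ``ne`` diploid parents per generation; each offspring draws two parents
    uniformly (selfing possible) and one allele per parent per locus. The
    finite parent pool generates the multilocus disequilibrium the LD-based
    Ne estimator measures. Initial frequencies are Uniform(0.2, 0.8).

    For very large ``ne`` the drift LD (~1/(3Ne)) is negligible and genotypes
    are drawn binomially from drifted frequencies instead, which is the exact
    no-LD limit and avoids simulating the full parent pool.
    """
    if ne < 2:
        raise ValueError("ne must be >= 2")
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    rng = substream_rng(seed, "wright_fisher")
    p0 = rng.uniform(0.2, 0.8, size=n_loci)
    locus_ids = [f"WF{j:05d}" for j in range(n_loci)]
    sample_ids = [f"S{i:04d}" for i in range(sample_size)]

    if ne > _LARGE_NE_CUTOFF:
        p = p0
        for _ in range(n_generations):
            p = rng.binomial(2 * ne, p) / (2.0 * ne)
        codes = rng.binomial(2, p[None, :], size=(sample_size, n_loci))
        return GenotypeMatrix(sample_ids, locus_ids, codes.astype(np.int8))

    # alleles: (ne, 2, n_loci) boolean = carries the focal allele
    alleles = rng.random((ne, 2, n_loci)) < p0[None, None, :]
    for _ in range(n_generations):
        mothers = rng.integers(0, ne, size=ne)
        fathers = rng.integers(0, ne, size=ne)
        pick_m = rng.integers(0, 2, size=(ne, n_loci))
        pick_f = rng.integers(0, 2, size=(ne, n_loci))
        gam_m = np.take_along_axis(alleles[mothers], pick_m[:, None, :], axis=1)[:, 0, :]
        gam_f = np.take_along_axis(alleles[fathers], pick_f[:, None, :], axis=1)[:, 0, :]
        alleles = np.stack([gam_m, gam_f], axis=1)

    mothers = rng.integers(0, ne, size=sample_size)
    fathers = rng.integers(0, ne, size=sample_size)
    pick_m = rng.integers(0, 2, size=(sample_size, n_loci))
    pick_f = rng.integers(0, 2, size=(sample_size, n_loci))
    gam_m = np.take_along_axis(alleles[mothers], pick_m[:, None, :], axis=1)[:, 0, :]
    gam_f = np.take_along_axis(alleles[fathers], pick_f[:, None, :], axis=1)[:, 0, :]
    codes = gam_m.astype(np.int8) + gam_f.astype(np.int8)
    return GenotypeMatrix(sample_ids, locus_ids, codes)
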
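"""Reproducible end-to-end benchmarks of the pipeline's core claims.

Each function regenerates its inputs from a master seed and measures the
pipeline on them: multiple-testing threshold, F_ST estimator recovery,
outlier-scan calibration and power, HWE exact-test agreement with a rational
enumeration oracle, mixed-model calibration and power, random-forest purge
recovery, and LD-based Ne recovery. Problem sizes are desk-scale versions of
the study design (the pair sample sizes and ~2,600-locus panel are kept;
forest sizes are reduced — see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd

from . import gwas_mlm as gw
from . import outlier_scan as osc
from . import popgen_stats as ps
from . import rf_purge as rf
from . import synthetic_data as synth
from .containers import RunConfig, substream_rng, substream_seed
from .genotype_qc import by_fdr_threshold, hwe_exact_test


def bench_by_threshold(m: int = 2593, q: float = 0.05) -> float:
    return by_fdr_threshold(m, q)


def bench_fst_recovery(seed: int, n_seeds: int = 20, n_loci: int = 2600,
                       n_per_group: int = 50) -> dict:
    """Mean multilocus theta on F-model pairs at targets 0 and 0.09."""
    out = {}
    for target in (0.0, 0.09):
        thetas = []
        for k in range(n_seeds):
            gm, st, _ = synth.simulate_pair(synth.PairScenario(
                n_anadromous=n_per_group, n_resident=n_per_group,
                n_loci=n_loci, fst_target=target,
                seed=substream_seed(seed, f"fst:{target}:{k}"),
                pair_label="bench"))
            comp = ps.wc_theta_locus(gm, st.population_of(gm.sample_ids))
            thetas.append(ps.multilocus_theta(comp))
        out[target] = float(np.mean(thetas))
    return out


def bench_scenario_fst(seed: int, n_seeds: int = 3) -> dict:
    """Multilocus theta of the two study-like scenarios (with planted loci)."""
    strong, flat = [], []
    for k in range(n_seeds):
        gm, st, _ = synth.simulate_pair(
            synth.redfish_like(seed=substream_seed(seed, f"scen_r:{k}")))
        strong.append(ps.multilocus_theta(
            ps.wc_theta_locus(gm, st.population_of(gm.sample_ids))))
        gm, st, _ = synth.simulate_pair(
            synth.alturas_like(seed=substream_seed(seed, f"scen_a:{k}")))
        flat.append(ps.multilocus_theta(
            ps.wc_theta_locus(gm, st.population_of(gm.sample_ids))))
    return {"strong": float(np.mean(strong)), "panmictic": float(np.mean(flat))}


def bench_outlier_scan(seed: int, n_neutral_seeds: int = 10,
                       n_planted_seeds: int = 10) -> dict:
    """Neutral false-call rate and planted-outlier recovery under BY-FDR."""
    cfg = RunConfig(seed=seed, null_sim_loci=10000)
    neutral_rates = []
    for k in range(n_neutral_seeds):
        s = substream_seed(seed, f"outlier_neutral:{k}")
        gm, st, _ = synth.simulate_pair(synth.PairScenario(
            n_anadromous=103, n_resident=45, n_loci=2000, fst_target=0.0,
            seed=s, pair_label="neu"))
        res = osc.scan(gm, st.population_of(gm.sample_ids), None,
                       cfg.with_overrides(seed=s))
        neutral_rates.append(float((res.table["class"] == "divergent").mean()))
    hits = total = 0
    fp = fp_total = 0
    for k in range(n_planted_seeds):
        s = substream_seed(seed, f"outlier_planted:{k}")
        gm, st, truth = synth.simulate_pair(synth.redfish_like(seed=s))
        res = osc.scan(gm, st.population_of(gm.sample_ids), None,
                       cfg.with_overrides(seed=s))
        tab = res.table.set_index("locus")
        planted = sorted(truth.outlier_locus_ids)
        scanned = [l for l in planted if l in tab.index]
        hits += int((tab.loc[scanned, "class"] == "divergent").sum())
        total += len(planted)
        bg = tab.drop(index=scanned)
        fp += int((bg["class"] == "divergent").sum())
        fp_total += len(bg)
    return {
        "neutral_divergent_rate": float(np.mean(neutral_rates)),
        "planted_recovery": hits / total,
        "false_positive_rate": fp / fp_total,
    }


def _hwe_rational_oracle(n_aa: int, n_het: int, n_bb: int) -> Fraction:
    """Levene conditional exact p, in exact rational arithmetic."""
    n = n_aa + n_het + n_bb
    n_a = 2 * n_aa + n_het
    n_minor = min(n_a, 2 * n - n_a)

    def prob(h: int) -> Fraction:
        aa = (n_a - h) // 2
        return Fraction(comb(n, h) * comb(n - h, aa) * 2**h, comb(2 * n, n_a))

    probs = {h: prob(h) for h in range(n_minor % 2, n_minor + 1, 2)}
    p_obs = probs[n_het]
    return sum(p for p in probs.values() if p <= p_obs)


def bench_hwe_oracle(max_n: int = 30) -> dict:
    """Max |implementation − rational oracle| over every configuration."""
    worst = 0.0
    count = 0
    for n in range(1, max_n + 1):
        for n_aa in range(n + 1):
            for n_het in range(n - n_aa + 1):
                n_bb = n - n_aa - n_het
                diff = abs(hwe_exact_test(n_aa, n_het, n_bb)
                           - float(_hwe_rational_oracle(n_aa, n_het, n_bb)))
                worst = max(worst, diff)
                count += 1
    return {"max_abs_err": worst, "n_configs": count}


def bench_gwas(seed: int, n_null_seeds: int = 5, n_power_seeds: int = 8) -> dict:
    """Genomic inflation on confounded null pairs; causal top-1% ranking."""
    lams = []
    for k in range(n_null_seeds):
        s = substream_seed(seed, f"gwas_null:{k}")
        gm, st, _ = synth.simulate_pair(synth.PairScenario(
            n_anadromous=60, n_resident=60, n_loci=1500, fst_target=0.09,
            seed=s, pair_label="nul"))
        pops = st.population_of(gm.sample_ids)
        rng = substream_rng(s, "confound")
        liab = 1.0 * (pops == pops[0]) + rng.standard_normal(gm.n_samples)
        st.table["life_history"] = (liab > np.median(liab)).astype(float)
        fit = gw.run_gwas(gm, st, RunConfig(seed=s))
        lams.append(gw.genomic_inflation(fit.marker_table["p"].to_numpy()))
    frac_top = []
    for k in range(n_power_seeds):
        s = substream_seed(seed, f"gwas_power:{k}")
        gm, st, truth = synth.simulate_pair(synth.alturas_like(seed=s))
        fit = gw.run_gwas(gm, st, RunConfig(seed=s))
        tab = fit.marker_table.set_index("locus")
        ranks = tab["p"].rank(method="min")
        top = ranks <= np.ceil(0.01 * len(tab))
        frac_top.append(float(top.loc[sorted(truth.causal_locus_ids)].mean()))
    return {"inflation": float(np.mean(lams)),
            "causal_top1pct": float(np.mean(frac_top))}


@dataclass
class RfBenchResult:
    run_recoveries: list[int]
    traces_valid: bool
    best_sizes: list[int]

    @property
    def frac_runs_recovering(self) -> float:
        return float(np.mean([r >= 4 for r in self.run_recoveries]))


def bench_rf_purge(seed: int, n_runs: int = 10, n_samples: int = 150,
                   n_noise: int = 45, n_trees: int = 100,
                   n_trees_escalated: int = 300) -> RfBenchResult:
    """Backward-purge recovery of 5 causal markers among noise.

    Residual-scale data: five markers jointly explain ~56% of the response
    (the scale of variance the study's best subsets explained), the rest is
    noise. A run recovers when >= 4 of the 5 are in the best subset.
    """
    recoveries = []
    valid = True
    sizes = []
    for k in range(n_runs):
        rng = substream_rng(seed, f"rf_bench:{k}")
        X = rng.standard_normal((n_samples, 5 + n_noise))
        y = X[:, :5] @ np.full(5, 0.5) + rng.standard_normal(n_samples)
        cols = [f"m{j:02d}" for j in range(5 + n_noise)]
        data = gw.ResidualData(y, pd.DataFrame(X, columns=cols),
                               [f"s{i}" for i in range(n_samples)])
        trace = rf.backward_purge(
            data, seed=substream_seed(seed, f"rf_purge:{k}"),
            n_trees=n_trees, n_trees_escalated=n_trees_escalated)
        best = trace.best_step()
        recoveries.append(len(set(best.markers) & set(cols[:5])))
        sizes.append(len(best.markers))
        for prev, nxt in zip(trace.steps, trace.steps[1:]):
            if set(nxt.markers) != set(prev.markers) - {prev.dropped}:
                valid = False
        if len(trace.steps[-1].markers) != 2:
            valid = False
    return RfBenchResult(recoveries, valid, sizes)


def bench_ne_recovery(seed: int, n_seeds: int = 20, true_ne: int = 100,
                      n_loci: int = 500, sample_size: int = 50,
                      n_generations: int = 12) -> dict:
    """LD-based Ne on Wright–Fisher simulations at known Ne."""
    estimates = []
    for k in range(n_seeds):
        gm = synth.simulate_wright_fisher(
            true_ne, n_loci, n_generations, sample_size,
            seed=substream_seed(seed, f"wf:{k}"))
        estimates.append(ps.ne_ld_estimate(gm).ne)
    est = np.asarray(estimates)
    in_range = float(((est >= 50) & (est <= 200)).mean())
    return {"frac_in_range": in_range, "median": float(np.median(est)),
            "estimates": [float(x) for x in est]}
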
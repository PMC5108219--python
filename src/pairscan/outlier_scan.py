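"""He-conditioned F_ST outlier detection against a simulated neutral null.

The null is the Balding–Nichols F-model calibrated to the trimmed neutral mean
theta of the observed data: loci are simulated at the observed group sample
sizes, the divergence parameter is rescaled once so the simulated multilocus
theta matches the target, and simulated loci are binned into 20 equal-count
expected-heterozygosity bins. Each observed locus gets an empirical p — the
(smoothed, mid-rank) probability that a simulated locus in its He bin has
theta at or below the observed value — so high p means unusually divergent.
Classification applies the Benjamini–Yekutieli threshold at both tails, and
the putatively neutral set is the loci with p inside a central band in all
three analyses (each pair, and all collections combined).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, RunConfig, substream_rng
from .genotype_qc import by_fdr_threshold
from .popgen_stats import _group_counts, multilocus_theta, wc_components, wc_theta_locus

logger = logging.getLogger("pairscan")

__all__ = [
    "NullDistribution",
    "OutlierResult",
    "calibrate_null",
    "empirical_pvalues",
    "classify_outliers",
    "neutral_set",
    "scan",
]

N_HE_BINS = 20
TAIL_TRIM = 0.05


@dataclass
class NullDistribution:
    sim_theta: np.ndarray
    sim_he: np.ndarray
    neutral_mean_theta: float
    c_used: float
    bin_edges: np.ndarray
    bin_of_sim: np.ndarray
    n_sim: int
    seed: int
    group_sizes: np.ndarray

    def bin_of(self, he: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.bin_edges[1:-1], he, side="right")
        return np.clip(idx, 0, N_HE_BINS - 1)


@dataclass
class OutlierResult:
    label: str
    table: pd.DataFrame  # locus, theta, He, p, class
    null: NullDistribution | None = None


def _mean_group_he(n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Sample-size-weighted mean within-group expected heterozygosity."""
    with np.errstate(invalid="ignore"):
        he = 2 * p * (1 - p)
        w = np.where(n > 0, n, 0.0)
        return np.nansum(w * he, axis=0) / np.maximum(w.sum(0), 1e-12)


def _simulate_null(rng: np.random.Generator, c: float, group_sizes: np.ndarray,
                   n_sim: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Simulate F-model loci at given group sizes.

    Returns per-locus theta, mean within-group He, and the ratio-of-sums
    multilocus theta of the simulated cloud.
    """
    r = len(group_sizes)
    p_anc = rng.uniform(0.05, 0.95, size=n_sim)
    if c <= 0:
        freqs = np.tile(p_anc, (r, 1))
    else:
        scale = (1.0 - c) / c
        freqs = rng.beta(p_anc * scale, (1.0 - p_anc) * scale, size=(r, n_sim))
    n = np.tile(np.asarray(group_sizes, float)[:, None], (1, n_sim))
    # genotype summaries per group: binomial sampling of diploids (HWE within)
    counts_het = np.empty((r, n_sim))
    counts_p = np.empty((r, n_sim))
    for g in range(r):
        geno = rng.binomial(2, freqs[g], size=(int(group_sizes[g]), n_sim))
        counts_p[g] = geno.mean(0) / 2.0
        counts_het[g] = (geno == 1).mean(0)
    a, b, cc = wc_components(n, counts_p, counts_het)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a + b + cc
        theta = np.where(denom != 0, a / denom, np.nan)
    he = _mean_group_he(n, counts_p)
    # trimmed ratio-of-sums, matching how the observed target is computed, so
    # the trim bias cancels in the one-pass rescaling
    ok = ~np.isnan(denom) & (denom != 0)
    multi = np.nan
    if ok.any():
        t, av, dv = theta[ok], a[ok], denom[ok]
        lo, hi = np.quantile(t, [TAIL_TRIM, 1 - TAIL_TRIM])
        keep = (t >= lo) & (t <= hi)
        if keep.any():
            multi = float(av[keep].sum() / dv[keep].sum())
    return theta, he, multi


def calibrate_null(gm: GenotypeMatrix, groups: np.ndarray, seed: int,
                   n_sim: int = 10000, seed_name: str = "outlier_null"
                   ) -> NullDistribution:
    """Build the simulated neutral (He, theta) cloud for the observed design.

    The target neutral mean excludes the 5% most extreme per-locus thetas at
    each tail (a one-pass stand-in for full iterative outlier removal); the
    F-model divergence parameter is rescaled once so the simulated multilocus
    theta matches the target within 0.005.
    """
    groups = np.asarray(groups)
    comp = wc_theta_locus(gm, groups)
    ok = comp.dropna(subset=["a", "b", "c"])
    if len(ok) < 50:
        raise ValueError("need at least 50 informative loci to calibrate the null")
    theta_locus = ok["theta"].to_numpy()
    lo, hi = np.quantile(theta_locus, [TAIL_TRIM, 1 - TAIL_TRIM])
    trimmed = ok[(ok["theta"] >= lo) & (ok["theta"] <= hi)]
    target = multilocus_theta(trimmed)

    labels = pd.unique(groups)
    group_sizes = np.array([(groups == lab).sum() for lab in labels], float)

    rng = substream_rng(seed, seed_name)
    if target <= 0:
        c = 1e-6
        logger.info("null target theta %.4f <= 0: degenerate panmictic null", target)
        theta, he, _ = _simulate_null(rng, c, group_sizes, n_sim)
    else:
        c = target
        theta, he, sim_mean = _simulate_null(rng, c, group_sizes, n_sim)
        if abs(sim_mean - target) > 0.005 and sim_mean > 0:
            c = min(c * target / sim_mean, 0.99)
            theta, he, _ = _simulate_null(rng, c, group_sizes, n_sim)

    valid = ~np.isnan(theta) & ~np.isnan(he)
    theta, he = theta[valid], he[valid]
    # 20 equal-count He bins
    edges = np.quantile(he, np.linspace(0, 1, N_HE_BINS + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    null = NullDistribution(
        sim_theta=theta, sim_he=he,
        neutral_mean_theta=float(target if target > 0 else 0.0),
        c_used=float(c), bin_edges=edges,
        bin_of_sim=np.clip(np.searchsorted(edges[1:-1], he, side="right"),
                           0, N_HE_BINS - 1),
        n_sim=int(theta.size), seed=seed, group_sizes=group_sizes,
    )
    return null


def empirical_pvalues(null: NullDistribution, observed: pd.DataFrame,
                      label: str = "analysis") -> OutlierResult:
    """Empirical p per observed locus: P(simulated theta <= observed | He bin).

    Add-one smoothing keeps p in (0, 1); ties between observed and simulated
    thetas count half (mid-rank). Loci falling in an empty He bin borrow the
    nearest populated bin, with a warning.
    """
    obs = observed.copy()
    bins = null.bin_of(obs["He"].to_numpy())
    populated = np.unique(null.bin_of_sim)
    p_out = np.full(len(obs), np.nan)
    for b in np.unique(bins):
        use_b = b
        if b not in populated:
            use_b = populated[np.argmin(np.abs(populated - b))]
            logger.warning("He bin %d empty in null; using bin %d", b, use_b)
        sims = null.sim_theta[null.bin_of_sim == use_b]
        sel = bins == b
        t_obs = obs.loc[sel, "theta"].to_numpy()
        less = (sims[None, :] < t_obs[:, None]).sum(1)
        equal = (sims[None, :] == t_obs[:, None]).sum(1)
        p_out[sel] = (1.0 + less + 0.5 * equal) / (1.0 + sims.size)
    obs["p"] = p_out
    return OutlierResult(label, obs, null)


def classify_outliers(result: OutlierResult, q: float = 0.05) -> OutlierResult:
    """Tag loci divergent (high-theta tail) or balancing (low-theta tail).

    A locus is divergent iff ``1 − p < by_fdr_threshold(m, q)`` and balancing
    iff ``p`` itself beats the threshold; everything else is a
    neutral-candidate.
    """
    table = result.table.copy()
    thr = by_fdr_threshold(len(table), q)
    p = table["p"].to_numpy()
    cls = np.full(len(table), "neutral-candidate", dtype=object)
    cls[(1.0 - p) < thr] = "divergent"
    cls[p < thr] = "balancing"
    table["class"] = cls
    table["by_threshold"] = thr
    return OutlierResult(result.label, table, result.null)


def scan(gm: GenotypeMatrix, groups: np.ndarray, which: list[str] | None,
         config: RunConfig, seed_name: str = "outliers") -> OutlierResult:
    """Calibrate, score and classify one analysis (a pair or all collections)."""
    groups = np.asarray(groups)
    if which is not None:
        mask = np.isin(groups, which)
        gm = gm.take_samples(np.flatnonzero(mask))
        groups = groups[mask]
    comp = wc_theta_locus(gm, groups)
    _, n, p, _h = _group_counts(gm, groups)
    comp["He"] = _mean_group_he(n, p)
    observed = comp.dropna(subset=["theta", "He"])[["locus", "theta", "He"]]
    null = calibrate_null(gm, groups, seed=config.seed,
                          n_sim=config.null_sim_loci, seed_name=seed_name)
    res = empirical_pvalues(null, observed, label=seed_name)
    return classify_outliers(res, q=config.fdr_q)


def neutral_set(tables: list[pd.DataFrame],
                band: tuple[float, float] = (0.1, 0.9)) -> set[str]:
    """Loci whose empirical p lies inside the closed band in ALL analyses.

    A locus absent from any analysis is excluded (and counted in the log).
    """
    if len(tables) < 2:
        raise ValueError("neutral set needs at least two analyses")
    lo, hi = band
    sets = []
    common: set[str] | None = None
    for t in tables:
        ids = set(t["locus"])
        common = ids if common is None else (common & ids)
        ok = t[(t["p"] >= lo) & (t["p"] <= hi)]
        sets.append(set(ok["locus"]))
    excluded = set.union(*[set(t["locus"]) for t in tables]) - common
    if excluded:
        logger.info("neutral set: %d loci missing from some analysis", len(excluded))
    out = common
    for s in sets:
        out = out & s
    return out
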
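"""Diversity statistics, Weir–Cockerham F_ST, PCA, pairwise LD and LD-based Ne.

F_ST uses the Weir & Cockerham (1984) variance-components estimator: per-locus
components ``a`` (among populations), ``b`` (among individuals within
populations) and ``c`` (within individuals), combined across loci as a ratio
of sums. Bootstrap confidence intervals resample loci. Effective population
size follows the bias-corrected linkage-disequilibrium method of Waples
(2006) / Waples & England (2011) on composite genotypic r².
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MISSING, GenotypeMatrix, substream_rng

logger = logging.getLogger("pairscan")

__all__ = [
    "DiversityStats",
    "FstResult",
    "NeEstimate",
    "heterozygosity_stats",
    "wc_components",
    "wc_theta_locus",
    "multilocus_theta",
    "fst_with_ci",
    "pca_genotypes",
    "PcaResult",
    "ld_r2",
    "ld_r2_matrix",
    "ne_ld_estimate",
]


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

@dataclass
class DiversityStats:
    per_locus: pd.DataFrame   # columns: locus, group, n, Ho, He, F
    summary: pd.DataFrame     # columns: group, Ho_mean, Ho_se, He_mean, ...


def _group_counts(gm: GenotypeMatrix, groups: np.ndarray
                  ) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Per group per locus: sample size, counted-allele frequency, het fraction."""
    labels = list(pd.unique(groups))
    n = np.zeros((len(labels), gm.n_loci))
    p = np.zeros_like(n)
    h = np.zeros_like(n)
    for g, lab in enumerate(labels):
        sub = gm.codes[groups == lab].astype(float)
        sub[sub == MISSING] = np.nan
        called = ~np.isnan(sub)
        n[g] = called.sum(0)
        with np.errstate(invalid="ignore"):
            p[g] = np.where(n[g] > 0, np.nansum(sub, 0) / (2 * np.maximum(n[g], 1)),
                            np.nan)
            h[g] = np.where(n[g] > 0,
                            np.nansum(sub == 1, 0) / np.maximum(n[g], 1), np.nan)
    return labels, n, p, h


def heterozygosity_stats(gm: GenotypeMatrix, groups: np.ndarray) -> DiversityStats:
    """Per-locus and mean±SE Ho, He (Nei unbiased) and F = 1 − Ho/He per group."""
    labels, n, p, h = _group_counts(gm, np.asarray(groups))
    rows = []
    for g, lab in enumerate(labels):
        if (n[g] >= 2).sum() == 0:
            raise ValueError(f"group {lab!r} has fewer than 2 genotyped individuals")
        with np.errstate(invalid="ignore", divide="ignore"):
            he = 2 * p[g] * (1 - p[g]) * (2 * n[g] / np.maximum(2 * n[g] - 1, 1))
            f = np.where(he > 0, 1 - h[g] / np.where(he > 0, he, np.nan), np.nan)
        df = pd.DataFrame({
            "locus": gm.locus_ids, "group": lab, "n": n[g],
            "Ho": h[g], "He": he, "F": f,
        })
        rows.append(df)
    per_locus = pd.concat(rows, ignore_index=True)

    def _mse(x: pd.Series) -> tuple[float, float]:
        x = x.dropna()
        return float(x.mean()), float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0

    summary_rows = []
    for lab in labels:
        sub = per_locus[per_locus["group"] == lab]
        row: dict = {"group": lab}
        for col in ("Ho", "He", "F"):
            mean, se = _mse(sub[col])
            row[f"{col}_mean"], row[f"{col}_se"] = mean, se
        summary_rows.append(row)
    return DiversityStats(per_locus, pd.DataFrame(summary_rows))


# ---------------------------------------------------------------------------
# Weir–Cockerham theta
# ---------------------------------------------------------------------------

def wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir–Cockerham (1984) a, b, c per locus from r-group summaries.

    Parameters are (r x L) arrays of per-group sample sizes, counted-allele
    frequencies and observed heterozygote fractions. Groups with no data at a
    locus are excluded there; loci with fewer than two informative groups get
    NaN components.
    """
    n = np.asarray(n, float)
    p = np.asarray(p, float)
    h = np.asarray(h, float)
    valid = (n > 0) & ~np.isnan(p)
    nv = np.where(valid, n, 0.0)
    pv = np.where(valid, p, 0.0)
    hv = np.where(valid, h, 0.0)
    r = valid.sum(0).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        nsum = nv.sum(0)
        nbar = nsum / r
        nc = (nsum - (nv**2).sum(0) / nsum) / (r - 1)
        pbar = (nv * pv).sum(0) / nsum
        s2 = (nv * (pv - pbar) ** 2).sum(0) / ((r - 1) * nbar)
        hbar = (nv * hv).sum(0) / nsum

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2

    bad = (r < 2) | (nbar <= 1)
    for arr in (a, b, c):
        arr[bad] = np.nan
    # monomorphic across all groups: uninformative
    mono = (pbar <= 0) | (pbar >= 1)
    mono &= (s2 == 0) | np.isnan(s2)
    for arr in (a, b, c):
        arr[mono & ~bad] = np.nan
    return a, b, c


def wc_theta_locus(gm: GenotypeMatrix, groups: np.ndarray
                   ) -> pd.DataFrame:
    """Per-locus theta components; theta = a / (a + b + c), negatives kept."""
    _, n, p, h = _group_counts(gm, np.asarray(groups))
    a, b, c = wc_components(n, p, h)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)
    return pd.DataFrame({"locus": gm.locus_ids, "a": a, "b": b, "c": c,
                         "theta": theta})


def multilocus_theta(components: pd.DataFrame) -> float:
    """Ratio-of-sums multilocus theta over informative loci."""
    ok = components[["a", "b", "c"]].notna().all(axis=1)
    a = components.loc[ok, "a"].to_numpy()
    denom = components.loc[ok, ["a", "b", "c"]].sum(axis=1).to_numpy()
    total = denom.sum()
    if ok.sum() < 1 or total == 0:
        return float("nan")
    return float(a.sum() / total)


@dataclass
class FstResult:
    label: str
    theta: float
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    reps: int
    n_loci: int
    per_locus: pd.DataFrame

    def as_row(self) -> dict:
        return {
            "pair": self.label, "theta": self.theta, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "p_value": self.p_value,
            "bootstrap_reps": self.reps, "n_loci": self.n_loci,
        }


def fst_with_ci(gm: GenotypeMatrix, groups: np.ndarray,
                which: list[str] | None = None, reps: int = 1000,
                seed: int = 1, label: str = "pair", alpha: float = 0.05
                ) -> FstResult:
    """Multilocus Weir–Cockerham theta with locus-bootstrap CI and p-value.

    The p-value is the fraction of bootstrap replicates with theta <= 0 (a
    one-sided test of differentiation). ``reps=0`` returns the point estimate
    only.
    """
    groups = np.asarray(groups)
    if which is not None:
        mask = np.isin(groups, which)
        gm = gm.take_samples(np.flatnonzero(mask))
        groups = groups[mask]
    comp = wc_theta_locus(gm, groups)
    ok = comp[["a", "b", "c"]].notna().all(axis=1)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 informative loci")
    theta = multilocus_theta(comp)
    if reps <= 0:
        return FstResult(label, theta, None, None, None, 0, int(ok.sum()), comp)
    rng = substream_rng(seed, f"fst_bootstrap:{label}")
    a = comp.loc[ok, "a"].to_numpy()
    denom = comp.loc[ok, ["a", "b", "c"]].sum(axis=1).to_numpy()
    L = len(a)
    idx = rng.integers(0, L, size=(reps, L))
    boot = a[idx].sum(1) / denom[idx].sum(1)
    lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    p = float((boot <= 0).mean())
    return FstResult(label, theta, float(lo), float(hi), p, reps, L, comp)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: np.ndarray              # n_samples x k
    explained_fraction: np.ndarray  # k

    def scores_frame(self, sample_ids: list[str]) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=sample_ids, columns=cols)


def pca_genotypes(gm: GenotypeMatrix, k: int | None = None) -> PcaResult:
    """PCA of mean-imputed, column-centred dosages (no scaling).

    Missing cells are replaced by the locus mean dosage (2p̂); columns are
    centred and the sample covariance eigen-decomposed via SVD. Components
    with numerically positive eigenvalues are returned.
    """
    if gm.n_samples < 2 or gm.n_loci < 2:
        raise ValueError("PCA needs at least 2 samples and 2 loci")
    X = gm.codes.astype(float)
    X[gm.missing_mask()] = np.nan
    mu = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mu, inds[1])
    X -= mu
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    eig = S**2 / (gm.n_samples - 1)
    pos = eig > eig[0] * 1e-12 if eig.size and eig[0] > 0 else np.zeros_like(eig, bool)
    if not pos.any():
        raise ValueError("constant genotype matrix: no positive eigenvalues")
    scores = U[:, pos] * S[pos]
    frac = eig[pos] / eig.sum()
    if k is not None:
        scores, frac = scores[:, :k], frac[:k]
    return PcaResult(scores, frac)


# ---------------------------------------------------------------------------
# LD and effective population size
# ---------------------------------------------------------------------------

def ld_r2(gm: GenotypeMatrix, locus_i: str | int, locus_j: str | int) -> float:
    """Composite LD: squared Pearson correlation of dosages, pairwise complete."""
    def _col(key):
        j = key if isinstance(key, (int, np.integer)) else gm.locus_ids.index(key)
        col = gm.codes[:, j].astype(float)
        col[col == MISSING] = np.nan
        return col

    x, y = _col(locus_i), _col(locus_j)
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return float("nan")
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_r2_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """All-pairs composite r² (complete-data fast path, NaN-aware otherwise)."""
    X = gm.codes.astype(float)
    X[gm.missing_mask()] = np.nan
    if not np.isnan(X).any():
        sd = X.std(0)
        keep_const = sd > 0
        R = np.full((gm.n_loci, gm.n_loci), np.nan)
        if keep_const.any():
            C = np.corrcoef(X[:, keep_const], rowvar=False)
            R[np.ix_(keep_const, keep_const)] = C**2
        return R
    df = pd.DataFrame(X)
    C = df.corr(min_periods=2).to_numpy()
    return C**2


@dataclass
class NeEstimate:
    r2_mean: float
    r2_drift: float
    ne: float
    ci_low: float
    ci_high: float
    s_harmonic: float
    n_pairs: int
    small_sample_branch: bool


def _ne_from_r2drift(r2d: float, small: bool) -> float:
    """Waples (2006) bias-corrected Ne from drift r²; inf when r2d <= 0."""
    if r2d <= 0:
        return float("inf")
    if small:
        disc = 0.308**2 - 2.08 * r2d
        if disc < 0:
            return 0.0
        return (0.308 + np.sqrt(disc)) / (2 * r2d)
    disc = 1.0 / 9.0 - 2.76 * r2d
    if disc < 0:
        return 0.0
    return (1.0 / 3.0 + np.sqrt(disc)) / (2 * r2d)


def ne_ld_estimate(gm: GenotypeMatrix, maf_min: float = 0.05,
                   alpha: float = 0.05) -> NeEstimate:
    """LD-based contemporary Ne from mean composite r² over unlinked pairs.

    The sampling expectation ``1/S + 3.19/S²`` (or the small-sample form
    ``0.0018 + 0.907/S + 4.44/S²`` when the harmonic mean sample size S < 30)
    is subtracted from mean r̂², and Waples' bias-corrected formula maps the
    drift residual to Ne. The CI is parametric: chi-square on mean r̂² with
    df = number of pairs.
    """
    from .genotype_qc import compute_maf

    maf = compute_maf(gm)
    keep = np.flatnonzero(~np.isnan(maf) & (maf >= maf_min))
    if keep.size < 2:
        raise ValueError("fewer than 2 loci pass the MAF cutoff")
    sub = gm.take_loci(keep)
    R = ld_r2_matrix(sub)
    iu = np.triu_indices(sub.n_loci, k=1)
    r2 = R[iu]
    ok = ~np.isnan(r2)
    r2 = r2[ok]
    n_pairs = int(r2.size)
    if n_pairs == 0:
        raise ValueError("no informative locus pairs")

    called = (sub.codes != MISSING).astype(float)
    per_locus_n = called.sum(0)
    # harmonic mean of pairwise sample sizes, approximated by per-locus min
    ni = per_locus_n[iu[0]][ok]
    nj = per_locus_n[iu[1]][ok]
    pair_n = np.minimum(ni, nj)
    S = float(len(pair_n) / np.sum(1.0 / pair_n))

    small = S < 30
    expected = (0.0018 + 0.907 / S + 4.44 / S**2) if small else (1.0 / S + 3.19 / S**2)
    r2_mean = float(r2.mean())
    r2_drift = r2_mean - expected
    ne = _ne_from_r2drift(r2_drift, small)

    df = n_pairs
    lo_r2 = r2_mean * df / stats.chi2.ppf(1 - alpha / 2, df)
    hi_r2 = r2_mean * df / stats.chi2.ppf(alpha / 2, df)
    # lower r² -> higher Ne
    ci_high = _ne_from_r2drift(lo_r2 - expected, small)
    ci_low = _ne_from_r2drift(hi_r2 - expected, small)
    if small:
        logger.info("LD-Ne: small-sample correction branch used (S=%.1f)", S)
    return NeEstimate(r2_mean, float(r2_drift), float(ne), float(ci_low),
                      float(ci_high), S, n_pairs, small)
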
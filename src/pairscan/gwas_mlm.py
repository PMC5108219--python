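"""Kinship-corrected association testing of a binary life-history trait.

The model is the standard single-variance-component linear mixed model
``y = Xβ + g + e`` with ``g ~ N(0, σ²_g K)`` and VanRaden genomic kinship K.
Variance components are estimated once by REML under the no-marker null via a
spectral decomposition of K (the EMMA trick) and reused for every marker test
(P3D). The binary phenotype is modelled as Gaussian 0/1, as the classical
GWAS frameworks for this design do. Fixed-effect candidates (sex, leading
principal components) enter by forward BIC selection. The same machinery
residualizes the phenotype and each marker for the downstream random-forest
stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import MISSING, GenotypeMatrix, RunConfig, SampleTable, substream_rng
from .genotype_qc import by_fdr_threshold
from .popgen_stats import pca_genotypes

logger = logging.getLogger("pairscan")

__all__ = [
    "KinshipMatrix",
    "MlmFit",
    "ResidualData",
    "impute_genotypes",
    "vanraden_kinship",
    "select_covariates",
    "fit_mlm_marker_tests",
    "residualize",
    "run_gwas",
    "residualize_fit",
    "genomic_inflation",
]


# ---------------------------------------------------------------------------
# imputation and kinship
# ---------------------------------------------------------------------------

def impute_genotypes(gm: GenotypeMatrix, subpopulations: np.ndarray, seed: int
                     ) -> GenotypeMatrix:
    """Fill missing cells with Binomial(2, p̂) draws, p̂ from the sample's
    subpopulation; falls back to the global frequency (warned) where a locus
    is entirely missing within a subpopulation."""
    subpopulations = np.asarray(subpopulations)
    if len(subpopulations) != gm.n_samples:
        raise ValueError("subpopulation labels must cover all samples")
    codes = gm.codes.astype(float)
    codes[codes == MISSING] = np.nan
    rng = substream_rng(seed, "impute_genotypes")
    global_p = gm.allele_freq()
    out = codes.copy()
    fallback = 0
    for pop in pd.unique(subpopulations):
        rows = subpopulations == pop
        block = codes[rows]
        with np.errstate(invalid="ignore"):
            n_called = (~np.isnan(block)).sum(0)
            p = np.where(n_called > 0, np.nansum(block, 0) / (2 * np.maximum(n_called, 1)),
                         np.nan)
        empty = np.isnan(p)
        fallback += int(empty.sum())
        p = np.where(empty, global_p, p)
        p = np.nan_to_num(p, nan=0.0)
        miss = np.isnan(block)
        if miss.any():
            draws = rng.binomial(2, np.broadcast_to(p, block.shape)[miss])
            block = block.copy()
            block[miss] = draws
        out[rows] = block
    if fallback:
        logger.warning("imputation: %d locus/subpopulation cells used the global "
                       "frequency", fallback)
    return GenotypeMatrix(list(gm.sample_ids), list(gm.locus_ids),
                          out.astype(np.int8))


def vanraden_kinship(gm: GenotypeMatrix) -> np.ndarray:
    """VanRaden genomic relationship matrix ``ZZᵀ / (2 Σ p̂(1−p̂))``."""
    if (gm.codes == MISSING).any():
        raise ValueError("kinship requires complete genotypes (impute first)")
    p = gm.allele_freq()
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic loci for kinship")
    Z = gm.codes[:, poly].astype(float) - 2 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1 - p[poly]))
    return (Z @ Z.T) / denom


KinshipMatrix = np.ndarray  # alias documenting intent


# ---------------------------------------------------------------------------
# REML machinery (EMMA spectral trick)
# ---------------------------------------------------------------------------

@dataclass
class _Spectral:
    """Eigen-decomposition of K with rotated responses."""

    eigvals: np.ndarray
    U: np.ndarray

    @classmethod
    def from_kinship(cls, K: np.ndarray) -> "_Spectral":
        K = np.asarray(K, float)
        K = (K + K.T) / 2.0
        vals, vecs = np.linalg.eigh(K)
        if vals.min() < -1e-8:
            logger.info("kinship not PSD (min eig %.2e): adding 1e-6 ridge", vals.min())
            vals = vals + 1e-6
        vals = np.clip(vals, 0.0, None)
        return cls(vals, vecs)

    def rotate(self, M: np.ndarray) -> np.ndarray:
        return self.U.T @ M


def _neg_reml(log_lam: float, yr: np.ndarray, Xr: np.ndarray, s: np.ndarray
              ) -> float:
    """Negative REML log-likelihood profiled over λ = σ²_g/σ²_e."""
    lam = np.exp(log_lam)
    w = lam * s + 1.0
    Xw = Xr / w[:, None]
    XtWX = Xr.T @ Xw
    try:
        beta = np.linalg.solve(XtWX, Xw.T @ yr)
    except np.linalg.LinAlgError:
        return 1e12
    resid = yr - Xr @ beta
    n, p = Xr.shape
    rss = float(resid @ (resid / w))
    if rss <= 0:
        return 1e12
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    _, logdet_XtX = np.linalg.slogdet(Xr.T @ Xr)
    ll = -0.5 * (
        (n - p) * (np.log(2 * np.pi * rss / (n - p)) + 1.0)
        + np.sum(np.log(w))
        + logdet_XtWX
        - logdet_XtX
    )
    return -ll


def _neg_ml(log_lam: float, yr: np.ndarray, Xr: np.ndarray, s: np.ndarray
            ) -> float:
    lam = np.exp(log_lam)
    w = lam * s + 1.0
    Xw = Xr / w[:, None]
    try:
        beta = np.linalg.solve(Xr.T @ Xw, Xw.T @ yr)
    except np.linalg.LinAlgError:
        return 1e12
    resid = yr - Xr @ beta
    n = len(yr)
    rss = float(resid @ (resid / w))
    if rss <= 0:
        return 1e12
    ll = -0.5 * (n * (np.log(2 * np.pi * rss / n) + 1.0) + np.sum(np.log(w)))
    return -ll


_LOG_LAM_GRID = np.linspace(-10, 10, 41)


def _optimize_lambda(yr: np.ndarray, Xr: np.ndarray, s: np.ndarray,
                     objective) -> tuple[float, float]:
    """Grid scan plus bounded refinement of the 1-D variance-ratio profile."""
    vals = [objective(g, yr, Xr, s) for g in _LOG_LAM_GRID]
    k = int(np.argmin(vals))
    lo = _LOG_LAM_GRID[max(k - 1, 0)]
    hi = _LOG_LAM_GRID[min(k + 1, len(_LOG_LAM_GRID) - 1)]
    res = optimize.minimize_scalar(objective, bounds=(lo, hi), method="bounded",
                                   args=(yr, Xr, s),
                                   options={"xatol": 1e-8})
    if res.fun <= vals[k]:
        return float(np.exp(res.x)), float(-res.fun)
    return float(np.exp(_LOG_LAM_GRID[k])), float(-vals[k])


@dataclass
class MlmFit:
    fixed_effects: list[str]
    lam: float                  # σ²_g / σ²_e at the null optimum
    sigma_g2: float
    sigma_e2: float
    loglik_reml: float
    marker_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # internals reused by residualization
    _spec: _Spectral | None = None
    _X: np.ndarray | None = None
    _y: np.ndarray | None = None
    _gm: GenotypeMatrix | None = None


@dataclass
class ResidualData:
    phenotype: np.ndarray
    genotypes: pd.DataFrame  # samples x markers, continuous residuals
    sample_ids: list[str]


# ---------------------------------------------------------------------------
# model selection, marker tests, residualization
# ---------------------------------------------------------------------------

def _design(n: int, candidates: dict[str, np.ndarray], chosen: list[str]
            ) -> np.ndarray:
    cols = [np.ones(n)]
    cols.extend(candidates[name] for name in chosen)
    return np.column_stack(cols)


def select_covariates(phenotype: np.ndarray, candidates: dict[str, np.ndarray],
                      K: np.ndarray, order: list[str] | None = None,
                      bic_margin: float = 2.0) -> list[str]:
    """Forward selection of fixed effects by ML BIC under the null MLM.

    Candidates are tried in a fixed order (sex first, then PCs by index); a
    term enters when it lowers BIC by more than ``bic_margin``.
    """
    y = np.asarray(phenotype, float)
    n = len(y)
    spec = _Spectral.from_kinship(K)
    yr = spec.rotate(y)
    order = order or list(candidates)
    chosen: list[str] = []

    def bic(names: list[str]) -> float:
        Xr = spec.rotate(_design(n, candidates, names))
        _, ll = _optimize_lambda(yr, Xr, spec.eigvals, _neg_ml)
        k = Xr.shape[1] + 2  # fixed effects + two variance components
        return -2.0 * ll + k * np.log(n)

    current = bic(chosen)
    for name in order:
        trial = bic(chosen + [name])
        if current - trial > bic_margin:
            chosen.append(name)
            current = trial
    return chosen


def fit_mlm_marker_tests(phenotype: np.ndarray, gm: GenotypeMatrix,
                         fixed: dict[str, np.ndarray], K: np.ndarray,
                         q: float = 0.05) -> MlmFit:
    """Per-marker Wald tests with null variance components reused (P3D).

    The no-marker null is fit by REML; each marker then enters the rotated
    GLS with the null λ fixed, which makes the scan deterministic and O(n)
    per marker.
    """
    y = np.asarray(phenotype, float)
    n = len(y)
    if gm.n_samples != n:
        raise ValueError("phenotype and genotypes must cover the same samples")
    if (gm.codes == MISSING).any():
        raise ValueError("marker tests require complete genotypes")
    spec = _Spectral.from_kinship(K)
    X = _design(n, fixed, list(fixed))
    yr = spec.rotate(y)
    Xr = spec.rotate(X)
    lam, ll = _optimize_lambda(yr, Xr, spec.eigvals, _neg_reml)
    w = lam * spec.eigvals + 1.0
    Xw = Xr / w[:, None]
    beta = np.linalg.solve(Xr.T @ Xw, Xw.T @ yr)
    resid = yr - Xr @ beta
    sigma_e2 = float(resid @ (resid / w)) / (n - X.shape[1])
    sigma_g2 = lam * sigma_e2

    Gr = spec.rotate(gm.codes.astype(float))
    p_fix = X.shape[1]
    dof = n - p_fix - 1
    effects = np.full(gm.n_loci, np.nan)
    ses = np.full(gm.n_loci, np.nan)
    pvals = np.ones(gm.n_loci)
    sw = np.sqrt(w)
    yw = yr / sw
    Xw_half = Xr / sw[:, None]
    for j in range(gm.n_loci):
        gj = Gr[:, j] / sw
        M = np.column_stack([Xw_half, gj])
        MtM = M.T @ M
        try:
            coef = np.linalg.solve(MtM, M.T @ yw)
            cov = np.linalg.inv(MtM) * sigma_e2
        except np.linalg.LinAlgError:
            continue
        se = float(np.sqrt(max(cov[-1, -1], 0.0)))
        if se == 0 or not np.isfinite(se):
            continue
        tstat = coef[-1] / se
        effects[j] = coef[-1]
        ses[j] = se
        pvals[j] = 2.0 * stats.t.sf(abs(tstat), dof)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    thr = by_fdr_threshold(gm.n_loci, q)
    table = pd.DataFrame({
        "locus": gm.locus_ids, "effect": effects, "se": ses, "p": pvals,
        "significant": pvals < thr,
    })
    return MlmFit(list(fixed), lam, sigma_g2, sigma_e2, ll, table,
                  _spec=spec, _X=X, _y=y, _gm=gm)


def _residualize_vector(spec: _Spectral, X: np.ndarray, lam: float,
                        v: np.ndarray) -> np.ndarray:
    """``v − Xβ̂ − BLUP`` under the fitted mixed model, via rotation."""
    vr = spec.rotate(v)
    Xr = spec.rotate(X)
    w = lam * spec.eigvals + 1.0
    Xw = Xr / w[:, None]
    beta = np.linalg.solve(Xr.T @ Xw, Xw.T @ vr)
    rr = vr - Xr @ beta
    # y − Xβ − ĝ = U diag(1/w) Uᵀ (y − Xβ)
    return spec.U @ (rr / w)


def residualize(phenotype: np.ndarray, gm: GenotypeMatrix,
                fixed: dict[str, np.ndarray], K: np.ndarray) -> ResidualData:
    """Residual phenotype and residual marker matrix for the RF stage.

    The phenotype uses its own REML λ; each marker column is treated as the
    response of the same model form (its λ re-optimized on the 1-D profile)
    and residualized identically.
    """
    y = np.asarray(phenotype, float)
    n = len(y)
    spec = _Spectral.from_kinship(K)
    X = _design(n, fixed, list(fixed))
    Xr = spec.rotate(X)
    yr = spec.rotate(y)
    lam_y, _ = _optimize_lambda(yr, Xr, spec.eigvals, _neg_reml)
    y_res = _residualize_vector(spec, X, lam_y, y)

    G = gm.codes.astype(float)
    Gr = spec.rotate(G)
    cols = {}
    for j, locus in enumerate(gm.locus_ids):
        lam_g, _ = _optimize_lambda(Gr[:, j], Xr, spec.eigvals, _neg_reml)
        cols[locus] = _residualize_vector(spec, X, lam_g, G[:, j])
    geno = pd.DataFrame(cols, index=gm.sample_ids)
    return ResidualData(y_res, geno, list(gm.sample_ids))


def genomic_inflation(pvalues: np.ndarray) -> float:
    """λ_GC: median marker chi-square over the null median (0.4549)."""
    p = np.asarray(pvalues, float)
    p = p[np.isfinite(p) & (p > 0) & (p <= 1)]
    chi2 = stats.chi2.ppf(1.0 - p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


# ---------------------------------------------------------------------------
# dataset-level driver
# ---------------------------------------------------------------------------

def run_gwas(gm: GenotypeMatrix, st: SampleTable, config: RunConfig,
             seed_name: str = "gwas", n_pcs: int = 3) -> MlmFit:
    """Impute, build kinship/PC/sex candidates, select covariates, scan markers."""
    sample_ids = gm.sample_ids
    pops = st.population_of(sample_ids)
    y = st.life_history_of(sample_ids)
    if np.isnan(y).any():
        raise ValueError("life_history must be defined for all GWAS samples")
    gm_c = impute_genotypes(gm, pops, seed=config.seed)
    K = vanraden_kinship(gm_c)
    pca = pca_genotypes(gm_c)
    k = min(n_pcs, pca.scores.shape[1])
    sex = st.sex_of(sample_ids)
    candidates: dict[str, np.ndarray] = {}
    if len(np.unique(sex[sex != "unknown"])) > 1:
        candidates["sex"] = (sex == "M").astype(float)
    for i in range(k):
        candidates[f"PC{i + 1}"] = pca.scores[:, i]
    chosen = select_covariates(y, candidates, K, order=list(candidates))
    logger.info("%s: selected covariates %s", seed_name, chosen or "none")
    fixed = {name: candidates[name] for name in chosen}
    fit = fit_mlm_marker_tests(y, gm_c, fixed, K, q=config.fdr_q)
    fit._gm = gm_c
    return fit


def residualize_fit(fit: MlmFit) -> ResidualData:
    """Residualize the data captured in a fitted GWAS."""
    if fit._gm is None or fit._spec is None:
        raise ValueError("fit does not carry its data")
    fixed = {}
    X = fit._X
    for i, name in enumerate(fit.fixed_effects):
        fixed[name] = X[:, i + 1]
    K = (fit._spec.U * fit._spec.eigvals) @ fit._spec.U.T
    return residualize(fit._y, fit._gm, fixed, K)
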
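"""Random-forest marker selection by triplicate importance and backward purging.

Regression forests are grown on residualized genotypes/phenotype. Importance
is permutation importance (mean increase in out-of-bag-style MSE when a
marker's column is shuffled), run in triplicate with distinct seed substreams;
if the minimum pairwise Pearson correlation between the three importance
vectors falls below 0.90 the triplicate is rerun with an escalated tree count.
The union of each replicate's top ~2% markers seeds a backward purge: at each
step triplicate forests are refit, the mean pseudo-R² (out-of-bag proportion
of response variance explained) is recorded, and the marker with the lowest
mean importance is dropped until two remain. The best subset maximizes mean
pseudo-R² (earliest step on ties).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .containers import RunConfig, substream_rng, substream_seed
from .gwas_mlm import ResidualData

logger = logging.getLogger("pairscan")

__all__ = [
    "ImportanceRun",
    "PurgeStep",
    "PurgeTrace",
    "rf_importance_converged",
    "select_top_union",
    "backward_purge",
    "purge_pipeline",
]


def _forest(n_trees: int, n_features: int, seed: int) -> RandomForestRegressor:
    # defaults of the classical RF regression implementation:
    # mtry = ceil(m/3), minimum node size 5, OOB error tracked
    return RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max(1, math.ceil(n_features / 3)),
        min_samples_leaf=5,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )


N_SHUFFLES = 8


def _n_shuffles(k: int) -> int:
    """Shuffle repeats per column: more for small panels, fewer for large.

    Averaging shuffles stabilizes the importance vector the way per-tree OOB
    permutation does; with thousands of columns the replicate-correlation
    statistic is already averaged over many values, so fewer repeats suffice
    and the k·n prediction cost stays bounded.
    """
    return int(np.clip(int(np.ceil(400 / max(k, 1))), 2, N_SHUFFLES))


def _permutation_importance(model: RandomForestRegressor, X: np.ndarray,
                            y: np.ndarray, rng: np.random.Generator,
                            n_shuffles: int | None = None) -> np.ndarray:
    """Mean increase in MSE when each column is permuted.

    Several shuffles per column are averaged — the classical OOB permutation
    importance effectively averages over every tree, and a single shuffle is
    too noisy for the replicate-agreement convergence rule. All permuted
    copies are stacked into chunked ``predict`` calls, which is far cheaper
    than per-column calls for the forest sizes used here.
    """
    n, k = X.shape
    if n_shuffles is None:
        n_shuffles = _n_shuffles(k)
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    base = np.mean((model.predict(X32) - y) ** 2)
    imp = np.zeros(k)
    # chunk the stacked permuted copies to bound memory at large marker counts
    max_cells = 40_000_000
    cols_per_chunk = max(1, max_cells // max(n_shuffles * n * k, 1))
    for start in range(0, k, cols_per_chunk):
        cols = range(start, min(start + cols_per_chunk, k))
        stack = np.tile(X32, (n_shuffles * len(cols), 1))
        for s in range(n_shuffles):
            for i, j in enumerate(cols):
                block = slice((s * len(cols) + i) * n, (s * len(cols) + i + 1) * n)
                stack[block, j] = rng.permutation(X32[:, j])
        pred = model.predict(stack)
        for s in range(n_shuffles):
            for i, j in enumerate(cols):
                block = slice((s * len(cols) + i) * n, (s * len(cols) + i + 1) * n)
                imp[j] += np.mean((pred[block] - y) ** 2) - base
    return imp / n_shuffles


@dataclass
class ImportanceRun:
    importances: pd.DataFrame  # markers x 3 replicates
    n_trees: int
    pairwise_r: list[float]
    converged: bool
    pseudo_r2: list[float]

    @property
    def mean_importance(self) -> pd.Series:
        return self.importances.mean(axis=1)

    @property
    def mean_pseudo_r2(self) -> float:
        return float(np.mean(self.pseudo_r2))


def _triplicate(X: np.ndarray, y: np.ndarray, markers: list[str], n_trees: int,
                seed: int, tag: str) -> ImportanceRun:
    imps = []
    r2s = []
    for rep in range(3):
        rep_seed = substream_seed(seed, f"rf:{tag}:rep{rep}")
        model = _forest(n_trees, X.shape[1], rep_seed)
        model.fit(X, y)
        rng = np.random.default_rng(rep_seed + 1)
        imps.append(_permutation_importance(model, X.copy(), y, rng))
        r2s.append(float(model.oob_score_))
    df = pd.DataFrame(np.column_stack(imps), index=markers,
                      columns=["rep1", "rep2", "rep3"])
    corr = []
    for i in range(3):
        for j in range(i + 1, 3):
            a, b = df.iloc[:, i], df.iloc[:, j]
            if a.std() == 0 or b.std() == 0:
                corr.append(1.0 if a.equals(b) else 0.0)
            else:
                corr.append(float(a.corr(b)))
    converged = min(corr) >= 0.90
    return ImportanceRun(df, n_trees, corr, converged, r2s)


def rf_importance_converged(data: ResidualData, n_trees_initial: int = 10000,
                            n_trees_escalated: int = 100000, seed: int = 1,
                            convergence_r: float = 0.90, tag: str = "full"
                            ) -> ImportanceRun:
    """Triplicate forests; escalate the tree count once if importances disagree.

    If the escalated triplicate still disagrees the run proceeds with a
    warning — there is no further escalation.
    """
    X = data.genotypes.to_numpy(dtype=float)
    y = np.asarray(data.phenotype, float)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 samples for the forest")
    markers = list(data.genotypes.columns)
    run = _triplicate(X, y, markers, n_trees_initial, seed, tag)
    if min(run.pairwise_r) >= convergence_r:
        return ImportanceRun(run.importances, run.n_trees, run.pairwise_r, True,
                             run.pseudo_r2)
    logger.info("rf %s: importance correlations %s < %.2f; escalating to %d trees",
                tag, [round(r, 3) for r in run.pairwise_r], convergence_r,
                n_trees_escalated)
    run = _triplicate(X, y, markers, n_trees_escalated, seed, f"{tag}:esc")
    converged = min(run.pairwise_r) >= convergence_r
    if not converged:
        logger.warning("rf %s: still unconverged after escalation (min r=%.3f); "
                       "proceeding", tag, min(run.pairwise_r))
    return ImportanceRun(run.importances, run.n_trees, run.pairwise_r, converged,
                         run.pseudo_r2)


def select_top_union(run: ImportanceRun, top_fraction: float = 0.02) -> list[str]:
    """Union over replicates of each replicate's top ``⌈fraction·m⌉`` markers."""
    m = run.importances.shape[0]
    k = max(1, math.ceil(top_fraction * m))
    chosen: set[str] = set()
    for col in run.importances.columns:
        top = run.importances[col].sort_values(ascending=False).index[:k]
        chosen.update(top)
    return sorted(chosen)


@dataclass
class PurgeStep:
    markers: tuple[str, ...]
    pseudo_r2: float
    dropped: str | None


@dataclass
class PurgeTrace:
    steps: list[PurgeStep]

    def best_step(self) -> PurgeStep:
        r2 = np.array([s.pseudo_r2 for s in self.steps])
        return self.steps[int(np.argmax(r2))]  # argmax returns earliest on ties

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "step": range(len(self.steps)),
            "n_markers": [len(s.markers) for s in self.steps],
            "pseudo_r2": [s.pseudo_r2 for s in self.steps],
            "dropped_next": [s.dropped for s in self.steps],
            "markers": [",".join(s.markers) for s in self.steps],
        })


def backward_purge(data: ResidualData, seed: int = 1, n_trees: int = 10000,
                   n_trees_escalated: int = 100000, convergence_r: float = 0.90
                   ) -> PurgeTrace:
    """Drop the least-important marker per step until two remain.

    Each step runs a convergence-checked triplicate on the current subset and
    records mean pseudo-R²; importance ties break lexicographically by marker
    id for determinism.
    """
    markers = list(data.genotypes.columns)
    if len(markers) < 3:
        raise ValueError("backward purge needs a starting subset of >= 3 markers")
    y = np.asarray(data.phenotype, float)
    steps: list[PurgeStep] = []
    current = sorted(markers)
    step_idx = 0
    while True:
        sub = ResidualData(y, data.genotypes[current], data.sample_ids)
        run = rf_importance_converged(
            sub, n_trees_initial=n_trees, n_trees_escalated=n_trees_escalated,
            seed=substream_seed(seed, f"purge:step{step_idx}"),
            convergence_r=convergence_r, tag=f"purge{step_idx}")
        mean_imp = run.mean_importance
        if len(current) == 2:
            steps.append(PurgeStep(tuple(current), run.mean_pseudo_r2, None))
            break
        # lowest mean importance; ties -> lexicographically first id
        lowest = mean_imp.reindex(sorted(current)).idxmin()
        steps.append(PurgeStep(tuple(current), run.mean_pseudo_r2, str(lowest)))
        current = [m for m in current if m != lowest]
        step_idx += 1
    return PurgeTrace(steps)


def purge_pipeline(data: ResidualData, config: RunConfig, seed: int = 1,
                   label: str = "dataset") -> PurgeTrace:
    """Full-model triplicate -> top-fraction union -> backward purge."""
    run = rf_importance_converged(
        data, n_trees_initial=config.rf_n_trees_initial,
        n_trees_escalated=config.rf_n_trees_escalated,
        seed=substream_seed(seed, f"rf_full:{label}"),
        convergence_r=config.rf_convergence_r, tag=label)
    subset = select_top_union(run, config.rf_top_fraction)
    if len(subset) < 3:
        # tiny panels: take the top 3 by mean importance so the purge can run
        subset = list(run.mean_importance.sort_values(ascending=False).index[:3])
    sub = ResidualData(np.asarray(data.phenotype, float),
                       data.genotypes[sorted(subset)], data.sample_ids)
    logger.info("rf %s: purging from %d markers", label, len(subset))
    return backward_purge(
        sub, seed=substream_seed(seed, f"rf_purge:{label}"),
        n_trees=config.rf_n_trees_initial,
        n_trees_escalated=config.rf_n_trees_escalated,
        convergence_r=config.rf_convergence_r)
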
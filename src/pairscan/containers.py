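"""Core in-memory containers shared by every pipeline stage.

Genotypes are held as an ``n_samples x n_loci`` integer matrix of minor- (or
reference-) allele dosages in ``{0, 1, 2}``, with :data:`MISSING` (-1) as the
missing sentinel.  Sample metadata travels in a plain pandas DataFrame wrapped
by :class:`SampleTable`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

SEX_LEVELS = ("M", "F", "unknown")


def substream_seed(master_seed: int, name: str) -> int:
    """Derive a named, reproducible child seed (< 2**31) from a master seed.

    Every stochastic stage pulls its generator from here so that one master
    seed pins down the whole pipeline while stages stay independent.
    """
    digest = hashlib.sha256(f"{int(master_seed)}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def substream_rng(master_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(substream_seed(master_seed, name))


@dataclass
class GenotypeMatrix:
    """Biallelic dosage matrix with sample and locus identifiers.

    Parameters
    ----------
    sample_ids, locus_ids
        Unique identifiers; lengths must match ``codes`` dimensions.
    codes
        Integer matrix, entries in {0, 1, 2} or :data:`MISSING`.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (samples x loci)")
        if self.codes.shape != (len(self.sample_ids), len(self.locus_ids)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.locus_ids)} loci"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("duplicate locus identifiers")
        valid = (self.codes == MISSING) | ((self.codes >= 0) & (self.codes <= 2))
        if not valid.all():
            bad = np.unique(self.codes[~valid])
            raise ValueError(f"invalid genotype codes: {bad.tolist()}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    # -- selection ------------------------------------------------------
    def take_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            list(self.locus_ids),
            self.codes[idx, :].copy(),
        )

    def take_loci(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            list(self.sample_ids),
            [self.locus_ids[j] for j in idx],
            self.codes[:, idx].copy(),
        )

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return self.take_samples([pos[s] for s in ids])

    def subset_loci(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {l: j for j, l in enumerate(self.locus_ids)}
        return self.take_loci([pos[l] for l in ids])

    # -- frequencies ----------------------------------------------------
    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele per locus (NaN if all missing)."""
        codes = self.codes.astype(float)
        codes[self.missing_mask()] = np.nan
        with np.errstate(invalid="ignore"):
            n_called = np.sum(~np.isnan(codes), axis=0)
            total = np.nansum(codes, axis=0)
            p = np.where(n_called > 0, total / (2.0 * np.maximum(n_called, 1)), np.nan)
        return p

    def orient_minor(self) -> "GenotypeMatrix":
        """Flip loci so codes count the globally minor allele.

        Ties at frequency 0.5 keep the current orientation, matching the
        canonical form produced by the genepop reader.
        """
        p = self.allele_freq()
        flip = p > 0.5
        codes = self.codes.copy()
        cols = codes[:, flip]
        obs = cols != MISSING
        cols[obs] = 2 - cols[obs]
        codes[:, flip] = cols
        return GenotypeMatrix(list(self.sample_ids), list(self.locus_ids), codes)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.codes.astype(float), index=self.sample_ids, columns=self.locus_ids
        )
        return df.mask(df < 0)


@dataclass
class SampleTable:
    """Per-individual population label, binary life history, and sex.

    ``life_history`` is 1 for anadromous (migratory) fish and 0 for resident
    Kokanee; it may be missing (NaN) for samples not entering association
    analyses.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "population", "life_history", "sex")

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                if col == "life_history":
                    df[col] = np.nan
                elif col == "sex":
                    df[col] = "unknown"
                else:
                    raise ValueError(f"sample table missing column {col!r}")
        df["sample_id"] = df["sample_id"].astype(str)
        df["population"] = df["population"].astype(str)
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample table")
        if (df["population"].str.len() == 0).any():
            raise ValueError("empty population label")
        bad_sex = ~df["sex"].isin(SEX_LEVELS)
        if bad_sex.any():
            raise ValueError(f"invalid sex values: {df.loc[bad_sex, 'sex'].unique()}")
        lh = df["life_history"]
        ok = lh.isna() | lh.isin([0, 1, 0.0, 1.0])
        if not ok.all():
            raise ValueError("life_history must be 0, 1 or missing")
        self.table = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def populations(self) -> pd.Series:
        return self.table.set_index("sample_id")["population"]

    def population_of(self, sample_ids: Sequence[str]) -> np.ndarray:
        pops = self.populations
        return np.asarray([pops[s] for s in sample_ids])

    def life_history_of(self, sample_ids: Sequence[str]) -> np.ndarray:
        lh = self.table.set_index("sample_id")["life_history"]
        return np.asarray([lh[s] for s in sample_ids], dtype=float)

    def sex_of(self, sample_ids: Sequence[str]) -> np.ndarray:
        sx = self.table.set_index("sample_id")["sex"]
        return np.asarray([sx[s] for s in sample_ids])

    def subset(self, sample_ids: Sequence[str]) -> "SampleTable":
        keep = self.table[self.table["sample_id"].isin(set(map(str, sample_ids)))]
        # preserve the requested order
        order = {s: i for i, s in enumerate(map(str, sample_ids))}
        keep = keep.sort_values("sample_id", key=lambda s: s.map(order))
        return SampleTable(keep.reset_index(drop=True))


@dataclass
class RunConfig:
    """Run-wide thresholds and sizes; defaults follow the study settings."""

    seed: int = 1
    maf_min: float = 0.05
    het_max: float = 0.80
    locus_missing_max: float = 0.30
    indiv_callrate_min: float = 0.75
    fdr_q: float = 0.05
    neutral_band: tuple[float, float] = (0.1, 0.9)
    bootstrap_reps: int = 1000
    null_sim_loci: int = 10000
    rf_n_trees_initial: int = 10000
    rf_n_trees_escalated: int = 100000
    rf_convergence_r: float = 0.90
    rf_top_fraction: float = 0.02

    def __post_init__(self) -> None:
        for name, lo, hi in [
            ("maf_min", 0.0, 0.5),
            ("het_max", 0.0, 1.0),
            ("locus_missing_max", 0.0, 1.0),
            ("indiv_callrate_min", 0.0, 1.0),
            ("fdr_q", 0.0, 1.0),
            ("rf_convergence_r", 0.0, 1.0),
            ("rf_top_fraction", 0.0, 1.0),
        ]:
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        lo, hi = self.neutral_band
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"invalid neutral band {self.neutral_band}")
        if self.bootstrap_reps < 0 or self.null_sim_loci < 0:
            raise ValueError("counts must be non-negative")
        self.seed = int(self.seed)

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)
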
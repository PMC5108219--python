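"""File formats and pipeline plumbing.

Reads and writes the two accepted genotype inputs — classic genepop text and a
plain TSV dosage matrix — plus the TSV sample table and a YAML run
configuration, and provides :func:`run_pipeline`, which chains every stage of
the analysis with a single master seed.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import MISSING, GenotypeMatrix, RunConfig, SampleTable

logger = logging.getLogger("pairscan")


class GenepopParseError(ValueError):
    pass


class BiallelicViolationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# genepop
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def _split_alleles(field: str, lineno: int) -> tuple[int, int]:
    field = field.strip()
    if len(field) == 4:
        width = 2
    elif len(field) == 6:
        width = 3
    else:
        raise GenepopParseError(
            f"line {lineno}: genotype field {field!r} is not 4 or 6 digits"
        )
    try:
        return int(field[:width]), int(field[width:])
    except ValueError as exc:
        raise GenepopParseError(f"line {lineno}: non-numeric genotype {field!r}") from exc


def read_genepop(path: str | Path) -> tuple[GenotypeMatrix, SampleTable]:
    """Parse a genepop file into a dosage matrix plus population labels.

    Allele codes may be 2- or 3-digit; ``00``/``000`` marks a missing allele.
    Per locus the globally minor allele is counted by the 0/1/2 code; ties at
    0.5 count the allele with the smaller numeric code.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise GenepopParseError("file too short to be genepop")
    # locus names: lines 2.. until first POP; a single line may be comma-separated
    locus_ids: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        chunk = [t.strip() for t in lines[i].split(",") if t.strip()]
        locus_ids.extend(chunk)
        i += 1
    if i == len(lines):
        raise GenepopParseError("no POP line found")
    n_loci = len(locus_ids)
    if len(set(locus_ids)) != n_loci:
        raise GenepopParseError("duplicate locus names")

    sample_ids: list[str] = []
    populations: list[str] = []
    allele_rows: list[list[tuple[int, int]]] = []
    pop_index = 0
    first_ids: list[str] = []
    while i < len(lines):
        if _POP_RE.match(lines[i]):
            pop_index += 1
            first_ids.append("")
            i += 1
            continue
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        if "," not in line:
            raise GenepopParseError(f"line {i + 1}: expected 'id , genotypes'")
        sid, _, geno_part = line.partition(",")
        sid = sid.strip()
        fields = geno_part.split()
        if len(fields) != n_loci:
            raise GenepopParseError(
                f"line {i + 1}: {len(fields)} genotype fields, expected {n_loci}"
            )
        alleles = [_split_alleles(f, i + 1) for f in fields]
        if not first_ids[-1]:
            first_ids[-1] = sid or f"pop{pop_index}"
        sample_ids.append(sid)
        populations.append(f"pop{pop_index}")
        allele_rows.append(alleles)
        i += 1
    if not sample_ids:
        raise GenepopParseError("no samples found")
    # genepop convention: populations are often named by their first/last sample id
    pop_names = {f"pop{k + 1}": (first_ids[k] or f"pop{k + 1}") for k in range(pop_index)}
    # disambiguate duplicated names
    seen: dict[str, int] = {}
    for key in sorted(pop_names):
        nm = pop_names[key]
        seen[nm] = seen.get(nm, 0) + 1
        if seen[nm] > 1:
            pop_names[key] = f"{nm}_{seen[nm]}"
    populations = [pop_names[p] for p in populations]

    if len(set(sample_ids)) != len(sample_ids):
        sample_ids = [f"{s}_{k}" for k, s in enumerate(sample_ids)]

    n = len(sample_ids)
    codes = np.full((n, n_loci), MISSING, dtype=np.int8)
    for j in range(n_loci):
        col = [allele_rows[r][j] for r in range(n)]
        observed = sorted({a for pair in col for a in pair if a != 0})
        if len(observed) > 2:
            raise BiallelicViolationError(
                f"locus {locus_ids[j]!r} has {len(observed)} alleles: {observed}"
            )
        if not observed:
            continue  # entirely missing locus
        if len(observed) == 1:
            # monomorphic: the minor allele is the unseen one, dosage 0
            for r, (x, y) in enumerate(col):
                if x != 0 and y != 0:
                    codes[r, j] = 0
            continue
        else:
            a1, a2 = observed
            cnt1 = sum((x == a1) + (y == a1) for x, y in col if x != 0 and y != 0)
            cnt2 = sum((x == a2) + (y == a2) for x, y in col if x != 0 and y != 0)
            # count the minor allele; tie -> smaller allele code
            counted = a1 if (cnt1 < cnt2 or (cnt1 == cnt2)) else a2
        for r, (x, y) in enumerate(col):
            if x == 0 or y == 0:
                continue
            codes[r, j] = int(x == counted) + int(y == counted)

    gm = GenotypeMatrix(sample_ids, locus_ids, codes)
    st = SampleTable(
        pd.DataFrame({"sample_id": sample_ids, "population": populations})
    )
    return gm, st


def write_genepop(gm: GenotypeMatrix, st: SampleTable, path: str | Path,
                  title: str = "pairscan export") -> None:
    """Write a 3-digit genepop file; missing genotypes become ``000000``.

    The counted allele is written as ``001`` and the other as ``002``, so a
    minor-allele-oriented matrix round-trips exactly. Samples are grouped by
    population in input order.
    """
    if gm.n_samples == 0 or gm.n_loci == 0:
        raise ValueError("refusing to write an empty genotype matrix")
    pops = st.population_of(gm.sample_ids)
    if any(p is None or p == "" or (isinstance(p, float) and np.isnan(p)) for p in pops):
        raise ValueError("every sample needs a population label")
    out = [title]
    out.extend(gm.locus_ids)
    # group samples by population, preserving first-appearance order
    order: list[str] = []
    for p in pops:
        if p not in order:
            order.append(p)
    # the counted allele is written as 001 so the reader's minor-allele rule
    # (ties -> smaller allele code) reproduces the codes exactly
    geno_str = {0: "002002", 1: "001002", 2: "001001", MISSING: "000000"}
    for p in order:
        out.append("POP")
        for i, sid in enumerate(gm.sample_ids):
            if pops[i] != p:
                continue
            fields = " ".join(geno_str[int(c)] for c in gm.codes[i])
            out.append(f"{sid} , {fields}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    """Read the tabular dialect: rows=samples, cols=loci, cells 0/1/2/NA."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    codes = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    out = np.full(codes.shape, MISSING, dtype=np.int8)
    called = ~np.isnan(codes)
    out[called] = codes[called].astype(np.int8)
    return GenotypeMatrix(list(df.index), list(df.columns), out)


def write_genotype_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    df = gm.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def read_sample_table(path: str | Path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population": str})
    return SampleTable(df)


def write_sample_table(st: SampleTable, path: str | Path) -> None:
    st.table.to_csv(path, sep="\t", index=False)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config file; keys mirror :class:`RunConfig` fields."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if "neutral_band" in data:
        data["neutral_band"] = tuple(data["neutral_band"])
    data.update(overrides)
    return RunConfig(**data)


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

def _pair_labels(st: SampleTable) -> list[tuple[str, list[str]]]:
    """Enumerate the analyses: each within-lake pair, then all collections.

    Populations are paired by a shared prefix before the first ``-`` or ``_``
    (e.g. ``Redfish-Anadromous`` / ``Redfish-Resident``); with exactly two
    populations there is a single pair.
    """
    pops = sorted(st.table["population"].unique())
    analyses: list[tuple[str, list[str]]] = []
    if len(pops) == 2:
        analyses.append((f"{pops[0]}_vs_{pops[1]}", pops))
    else:
        prefixes: dict[str, list[str]] = {}
        for p in pops:
            prefixes.setdefault(re.split(r"[-_]", p)[0], []).append(p)
        for pref, group in sorted(prefixes.items()):
            if len(group) == 2:
                analyses.append((pref, group))
    if len(pops) > 2:
        analyses.append(("combined", pops))
    return analyses


def run_pipeline(config: RunConfig, genotype_path: str | Path,
                 sample_table_path: str | Path, out_dir: str | Path) -> dict:
    """QC -> diversity/F_ST -> outlier scans -> GWAS -> RF purge, end to end.

    Writes per-stage TSV tables plus ``summary.json`` and ``run.log`` under
    ``out_dir`` and returns the summary dict. Any stage failure raises with
    the stage name attached.
    """
    from . import genotype_qc, gwas_mlm, outlier_scan, popgen_stats, rf_purge

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    summary: dict = {"config": {k: getattr(config, k) for k in vars(config)}}
    logger.info("config: %s", summary["config"])

    stage = "load"
    try:
        genotype_path = Path(genotype_path)
        if not Path(sample_table_path).exists():
            raise FileNotFoundError(sample_table_path)
        if genotype_path.suffix in {".tsv", ".txt"}:
            gm = read_genotype_tsv(genotype_path)
        else:
            gm, _ = read_genepop(genotype_path)
        st = read_sample_table(sample_table_path)
        st = st.subset(gm.sample_ids)

        stage = "qc"
        gm_qc, report = genotype_qc.apply_filters(gm, st, config)
        report.to_tsv(out / "qc_report.tsv")
        summary["qc"] = {
            "n_samples": gm_qc.n_samples,
            "n_loci": gm_qc.n_loci,
            "removed": report.removed_counts,
        }
        st = st.subset(gm_qc.sample_ids)
        analyses = _pair_labels(st)
        pops = st.population_of(gm_qc.sample_ids)

        stage = "popgen"
        div = popgen_stats.heterozygosity_stats(gm_qc, pops)
        div.per_locus.to_csv(out / "diversity_per_locus.tsv", sep="\t", index=False)
        div.summary.to_csv(out / "diversity_summary.tsv", sep="\t", index=False)
        fst_rows = []
        for label, group in analyses:
            if len(group) != 2:
                continue
            res = popgen_stats.fst_with_ci(
                gm_qc, pops, group, reps=config.bootstrap_reps,
                seed=config.seed, label=label)
            fst_rows.append(res.as_row())
        fst_table = pd.DataFrame(fst_rows)
        fst_table.to_csv(out / "fst_pairs.tsv", sep="\t", index=False)
        summary["fst"] = fst_table.to_dict("records")
        pca = popgen_stats.pca_genotypes(gm_qc)
        pca.scores_frame(gm_qc.sample_ids).to_csv(out / "pca_scores.tsv", sep="\t")

        stage = "outliers"
        outlier_tables = {}
        for label, group in analyses:
            res = outlier_scan.scan(
                gm_qc, pops, group, config=config,
                seed_name=f"outliers:{label}")
            res.table.to_csv(out / f"outliers_{label}.tsv", sep="\t", index=False)
            outlier_tables[label] = res
        summary["outliers"] = {
            label: {
                "n_divergent": int((r.table["class"] == "divergent").sum()),
                "n_balancing": int((r.table["class"] == "balancing").sum()),
            }
            for label, r in outlier_tables.items()
        }
        if len(outlier_tables) == 3:
            neutral = outlier_scan.neutral_set(
                [r.table for r in outlier_tables.values()],
                band=config.neutral_band)
            (out / "neutral_loci.txt").write_text("\n".join(sorted(neutral)) + "\n")
            summary["n_neutral"] = len(neutral)

        stage = "gwas"
        lh_all = st.life_history_of(gm_qc.sample_ids)
        summary["gwas"] = {}
        gwas_fits = {}
        for label, group in analyses:
            mask = np.isin(pops, group) & ~np.isnan(lh_all)
            sub = gm_qc.take_samples(np.flatnonzero(mask))
            fit = gwas_mlm.run_gwas(
                sub, st.subset(sub.sample_ids), config,
                seed_name=f"gwas:{label}")
            fit.marker_table.to_csv(out / f"gwas_{label}.tsv", sep="\t", index=False)
            gwas_fits[label] = (fit, sub)
            summary["gwas"][label] = {
                "covariates": fit.fixed_effects,
                "n_significant": int(fit.marker_table["significant"].sum()),
            }

        stage = "rfpurge"
        summary["rf"] = {}
        for label, (fit, sub) in gwas_fits.items():
            resid = gwas_mlm.residualize_fit(fit)
            trace = rf_purge.purge_pipeline(
                resid, config, seed=config.seed, label=label)
            trace.to_frame().to_csv(out / f"rf_purge_{label}.tsv", sep="\t", index=False)
            best = trace.best_step()
            summary["rf"][label] = {
                "best_markers": sorted(best.markers),
                "best_pseudo_r2": best.pseudo_r2,
            }
    except Exception as exc:
        logger.removeHandler(handler)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    logger.removeHandler(handler)
    return summary
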
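"""Readers, writers and the end-to-end pipeline.

All genomic intervals are 0-based half-open internally (BED native; VCF
positions are converted from 1-based).  Sample identifiers are checked for
consistency across tables — the intersection is reported and mismatches are
warned, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from cyvcf2 import VCF

from .config import GenotypeTriple, PipelineConfig, SNP_IDS
from . import alsfrs, footprint, haplotypes, outliers, progression

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""


@dataclass
class CohortTables:
    """Every input table the pipeline consumes."""

    genotypes: dict  # sample -> GenotypeTriple
    clinical: pd.DataFrame
    visits: pd.DataFrame
    expression: pd.DataFrame
    junctions: pd.DataFrame
    allele_counts: pd.DataFrame
    peaks: pd.DataFrame
    cuts: pd.DataFrame
    variants: Optional[pd.DataFrame] = None
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self):
        sets = {
            "genotypes": set(self.genotypes),
            "clinical": set(self.clinical["sample"]) if len(self.clinical) else set(),
            "expression": set(self.expression.columns),
        }
        common = set.intersection(*sets.values()) if sets else set()
        logger.info("sample intersection across tables: %d", len(common))
        for name, s in sets.items():
            extra = s - common
            if extra:
                logger.warning("%d samples only partially covered (e.g. in %s)", len(extra), name)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_genotypes(path, snp_ids: Sequence[str] = SNP_IDS) -> dict:
    """Read unphased genotypes at the requested SNP ids from a VCF.

    Phase separators are ignored; missing genotypes are flagged as ``None``
    in the triple.  A requested id that is absent, or a multiallelic record
    at a requested id, is a hard error.
    """
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    found: dict = {}
    for rec in vcf:
        if rec.ID not in snp_ids:
            continue
        if len(rec.ALT) != 1:
            raise ValueError(f"multiallelic record at {rec.ID}")
        alleles = [rec.REF] + list(rec.ALT)
        pairs = []
        for g in rec.genotypes:  # [a0, a1, phased]
            a0, a1 = g[0], g[1]
            if a0 < 0 or a1 < 0:
                pairs.append(None)
            else:
                pairs.append(tuple(sorted((alleles[a0], alleles[a1]))))
        found[rec.ID] = pairs
    missing = [s for s in snp_ids if s not in found]
    if missing:
        raise ValueError(f"SNP not found: {', '.join(missing)}")
    out = {}
    for i, smp in enumerate(sample_ids):
        out[smp] = GenotypeTriple(*[found[s][i] for s in snp_ids])
    return out


def read_clinical(
    path, onset_sites: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Read the clinical table; drop rows with missing or non-positive
    survival (count logged) and optionally filter by onset site."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"duplicated patient id: {dup}")
    surv = pd.to_numeric(df["survival_months"], errors="coerce")
    keep = surv.notna() & (surv > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_clinical: dropped %d rows without positive survival", n_dropped)
    df = df[keep].copy()
    df["survival_months"] = surv[keep]
    if onset_sites is not None:
        before = len(df)
        df = df[df["onset_site"].isin(onset_sites)]
        logger.info("read_clinical: onset-site filter retained %d of %d", len(df), before)
    return df.reset_index(drop=True)


def read_visits(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample": str})


def read_matrix(path, index_name: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).rename_axis(index_name)


def read_allele_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample": str})


def read_peaks(path) -> pd.DataFrame:
    """BED peak set -> DataFrame (chrom, start, end, peak_id), 0-based."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "peak_id"],
    )
    return df


def read_cuts(path) -> pd.DataFrame:
    """BED6 of read 5' ends (name column = sample) -> cut-event frame."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "sample", "score", "strand"],
    )
    return df.rename(columns={"start": "pos"})[["sample", "chrom", "pos", "strand"]]


def read_variants(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample": str})


def read_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def load_cohort_tables(directory, config: Optional[PipelineConfig] = None) -> CohortTables:
    """Load every table from a directory written by the synthetic generator
    (or laid out the same way)."""
    d = Path(directory)
    config = config or PipelineConfig()
    cov_path = d / "covariates.tsv"
    var_path = d / "variants.tsv"
    return CohortTables(
        genotypes=read_genotypes(d / "genotypes.vcf", config.snp_ids),
        clinical=read_clinical(d / "clinical.tsv", onset_sites=config.onset_sites),
        visits=read_visits(d / "visits.tsv"),
        expression=read_matrix(d / "expression.tsv", "gene"),
        junctions=read_matrix(d / "junctions.tsv", "junction"),
        allele_counts=read_allele_counts(d / "allele_counts.tsv"),
        peaks=read_peaks(d / "peaks.bed"),
        cuts=read_cuts(d / "cuts.bed"),
        variants=read_variants(var_path) if var_path.exists() else None,
        covariates=read_covariates(cov_path) if cov_path.exists() else None,
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _genotype_string(triple: GenotypeTriple) -> str:
    return "/".join("".join(p) if p else ".." for p in triple.pairs())


def _stage(name):
    def deco(fn):
        def wrapper(*a, **k):
            try:
                return fn(*a, **k)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


@_stage("haplotypes")
def stage_haplotypes(config: PipelineConfig, tables: CohortTables):
    gts = list(tables.genotypes.values())
    if not gts:
        raise ValueError("empty genotype table")
    rows = []
    for label, sel in [("2snp", (0, 1)), ("3snp", (0, 1, 2))]:
        est = haplotypes.em_haplotype_frequencies(
            gts, snps=sel, tol=config.em_tol, max_iter=config.em_max_iter
        )
        missing = set(map(tuple, haplotypes.detect_missing_haplotype(
            est, eps=config.missing_haplotype_eps)))
        for hap, f in est.freqs.items():
            rows.append({
                "selection": label,
                "haplotype": "".join(hap),
                "frequency": f,
                "missing": tuple(hap) in missing,
                "log_likelihood": est.log_likelihood,
                "iterations": est.iterations,
                "converged": est.converged,
            })
    nesting = haplotypes.test_rare_allele_nesting(gts)
    return pd.DataFrame(rows), nesting


@_stage("subgroups")
def stage_subgroups(config: PipelineConfig, tables: CohortTables):
    hre_map = {}
    if "hre_carrier" in tables.clinical.columns:
        hre_map = dict(zip(tables.clinical["sample"],
                           tables.clinical["hre_carrier"].astype(bool)))
    rows = []
    for smp, triple in tables.genotypes.items():
        hre = bool(hre_map.get(smp, False))
        code = wta = diag = None
        if hre:
            try:
                sg = haplotypes.assign_wta_subgroup(triple, hre_carrier=True)
                code, wta = sg.code, "".join(sg.wta_haplotype)
                diag = sg.label
            except (haplotypes.HREIncompatibleGenotypeError,
                    haplotypes.NonFounderWTAError, ValueError) as exc:
                diag = str(exc)
        else:
            diag = haplotypes.diplotype_label(triple) or "ambiguous"
        rows.append({
            "sample": smp,
            "genotype": _genotype_string(triple),
            "hre_carrier": int(hre),
            "subgroup_code": code if code is not None else "",
            "wta_haplotype": wta or "",
            "diagnostics": diag,
        })
    return pd.DataFrame(rows)


@_stage("survival")
def stage_survival(config: PipelineConfig, tables: CohortTables, subgroups: pd.DataFrame):
    clin = tables.clinical.merge(subgroups, on="sample", suffixes=("", "_sg"))
    clin = clin[clin["status"] == "case"] if "status" in clin.columns else clin
    # trim extremes of survival before any subgroup-specific analysis
    kept = progression.trim_extremes(
        clin["survival_months"].to_numpy(float), config.trim_fraction
    )
    clin = clin.iloc[kept]
    carriers = clin[clin["hre_carrier"].astype(bool)]
    carriers = carriers[carriers["subgroup_code"] != ""]
    model_df = pd.DataFrame({
        "survival_months": carriers["survival_months"].astype(float),
        "subgroup_code": carriers["subgroup_code"].astype(int),
    })
    eff = progression.subgroup_survival_model(model_df)
    model_tbl = pd.DataFrame([{
        "term": "subgroup_code",
        "estimate_log10_months_per_code": eff.estimate,
        "se": eff.se,
        "p": eff.p,
        "n": eff.n,
        "transform": eff.transform,
    }])
    diff_tbl = progression.genotype_difference_table(
        clin.assign(hre_carrier=clin["hre_carrier"].astype(bool)),
        genotype_col="genotype",
    )
    return model_tbl, diff_tbl


@_stage("alsfrs")
def stage_alsfrs(config: PipelineConfig, tables: CohortTables, subgroups: pd.DataFrame):
    code_map = {
        r["sample"]: int(r["subgroup_code"])
        for _, r in subgroups.iterrows()
        if r["subgroup_code"] != "" and pd.notna(r["subgroup_code"])
    }
    groups: dict = {}
    for smp, grp in tables.visits.groupby("sample"):
        if smp not in code_map:
            continue
        death = grp["death_month"].dropna()
        death_month = float(death.iloc[0]) if len(death) else None
        series = alsfrs.build_anchored_series(
            smp,
            list(zip(grp["months_from_onset"], grp["alsfrs_total"])),
            death_month=death_month,
        )
        groups.setdefault(code_map[smp], []).append(series)
    all_series = [s for g in groups.values() for s in g]
    tt = alsfrs.threshold_table(all_series, config.alsfrs_threshold, config.trim_fraction)
    tt = tt.merge(
        pd.Series(code_map, name="subgroup_code").rename_axis("patient_id").reset_index(),
        on="patient_id",
    )
    lo, hi = config.alsfrs_scan_range
    scan = alsfrs.threshold_scan(groups, range(lo, hi + 1), config.trim_fraction)
    traj = alsfrs.group_trajectories(
        groups, list(range(lo, hi + 1, 3)), config.trim_fraction
    )
    return tt, scan, traj


@_stage("footprint")
def stage_footprint(config: PipelineConfig, tables: CohortTables):
    shifted = footprint.shift_cuts(tables.cuts)
    samples = sorted(tables.genotypes)
    matrix = footprint.tabulate_cuts(shifted, tables.peaks, samples=samples)
    dose = {
        s: haplotypes.alt_dose(t, "rs2492816")
        for s, t in tables.genotypes.items()
    }
    dose = {s: d for s, d in dose.items() if d is not None}
    filtered = footprint.stack_and_filter([matrix])
    filtered.counts = filtered.counts[sorted(dose)]
    cov = None
    if tables.covariates is not None:
        cov = tables.covariates.loc[sorted(dose), list(config.footprint_covariates)]
        cov = pd.get_dummies(cov, drop_first=True, dtype=float)
    effects = footprint.per_base_dose_test(filtered, dose, covariates=cov)
    profiles = {}
    for pk in matrix.peak_totals.index:
        profiles[pk] = footprint.genotype_profiles(matrix, dose, pk)
    return effects, profiles


@_stage("outliers")
def stage_outliers(config: PipelineConfig, tables: CohortTables):
    calls = outliers.iqr_outliers(
        tables.expression, config.candidate_genes, k=config.outlier_iqr_k
    )
    ase_records = []
    for (smp, gene), grp in tables.allele_counts.groupby(["sample", "gene"]):
        counts = list(zip(grp["ref_count"], grp["alt_count"]))
        if sum(r + a for r, a in counts) == 0:
            continue
        ase_records.append(outliers.allele_balance(smp, gene, counts))
    ase = outliers.rank_allele_balance(ase_records)
    junc = outliers.unique_junctions(
        tables.junctions,
        min_count=config.junction_min_count,
        noise_count=config.junction_noise_count,
        variants=tables.variants,
        window=config.junction_window,
    )
    return calls, ase, junc


def run_pipeline(config: PipelineConfig, tables: CohortTables, out_dir) -> dict:
    """Run every stage and write the result tables; identical config and
    inputs yield byte-identical outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}

    def save(name, df):
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written[name] = p

    hap_tbl, nesting = stage_haplotypes(config, tables)
    save("haplotype_frequencies", hap_tbl)

    subgroups = stage_subgroups(config, tables)
    save("subgroups", subgroups)

    model_tbl, diff_tbl = stage_survival(config, tables, subgroups)
    save("survival_model", model_tbl)
    save("survival_differences", diff_tbl)

    tt, scan, traj = stage_alsfrs(config, tables, subgroups)
    save("time_to_threshold", tt)
    save("threshold_scan", scan)
    save("group_trajectories", traj)

    effects, profiles = stage_footprint(config, tables)
    save("footprint_effects", effects)

    calls, ase, junc = stage_outliers(config, tables)
    save("outlier_calls", calls)
    save("ase_ranking", ase)
    save("junction_events", junc)

    log_p = out / "pipeline.log"
    with open(log_p, "w") as fh:
        fh.write("rare-allele nesting: %r\n" % {k: v for k, v in nesting.items()
                                                if k != "incompatible_indices"})
        fh.write("tables written: %s\n" % ", ".join(sorted(written)))
    written["log"] = log_p
    return written
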
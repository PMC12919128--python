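"""Synthetic cohort generator.

Emulates the statistical structure the modifier analysis assumes, so every
downstream stage has planted ground truth:

* three founder haplotypes over rs2492816/rs13691 — the A/A combination is
  absent — with the rare rs113860022-G allele nested inside the G/A
  ("C9-low") background;
* the repeat expansion (HRE) co-inherited with the A/G/C haplotype, so each
  carrier's wild-type allele is one of the four founders;
* additive per-allele *C9orf72* expression effects plus a negative HRE
  shift;
* log10-scale survival in cases depending on the carrier's WTA subgroup
  code and HRE status, parameterised so the implied month-scale deficits of
  carriers vs genotype-matched non-carriers equal the published 18- and
  8-month values at codes 0 and 3;
* piecewise-linear ALSFRS-R decline from 48 at onset to 0 at death, with
  visit noise;
* negative-binomial per-base Tn5 cut counts with a genotype-dependent
  planted footprint in one peak;
* planted low-expression outliers, a carrier-unique splice junction tied to
  a rare intronic variant, and one allele-balance outlier.

Defaults reproduce the study's marginal allele frequencies (0.41 / 0.22 /
0.011) and per-allele expression slopes (+0.086, −0.081, −0.16).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .config import (
    DEFAULT_CANDIDATE_GENES,
    FOUNDER_CODES,
    GenotypeTriple,
    HRE_HAPLOTYPE,
    SNP_ALLELES,
    SNP_IDS,
)

FOUNDERS = list(FOUNDER_CODES)  # (G,A,G), (G,A,C), (G,G,C), (A,G,C)

#: genomic coordinates used for the synthetic VCF/BED files (1-based VCF pos)
SNP_POSITIONS = {"rs2492816": 27_540_000, "rs113860022": 27_573_000, "rs13691": 27_575_000}
CHROM = "chr9"


@dataclass
class GeneratorParams:
    """All planted parameters of the synthetic cohort."""

    # founder haplotype frequencies, FOUNDERS order: SL, L, M, H
    founder_freqs: tuple = (0.011, 0.209, 0.37, 0.41)
    hre_prevalence: float = 0.08  # fraction of ALS cases carrying the HRE

    # expression model (batch-corrected units)
    expression_baseline: float = 0.0
    #: per-alt-allele effects for rs2492816-A, rs13691-A, rs113860022-G
    expression_effects: tuple = (0.086, -0.081, -0.16)
    hre_expression_shift: float = -0.3
    expression_noise_sd: float = 0.1

    # survival model: log10(months) = baseline + code_effect*code (carriers)
    #                                + hre_effect (carriers) + N(0, sd)
    survival_baseline_log10: float = 1.5
    survival_noise_sd: float = 0.15
    #: month-scale survival deficits of carriers vs genotype-matched
    #: non-carriers at subgroup codes 0 and 3; the log-scale coefficients
    #: are derived from these
    hre_month_deficit_code0: float = -18.0
    hre_month_deficit_code3: float = -8.0
    survival_code_effect: float = field(init=False)
    survival_hre_effect: float = field(init=False)

    # ALSFRS-R visits
    visit_spacing_months: float = 3.0
    alsfrs_noise_sd: float = 2.0

    # per-base Tn5 cut model
    peaks: tuple = (
        (CHROM, 27_572_900, 27_573_200, "peak_promoter"),
        (CHROM, 27_560_000, 27_560_300, "peak_null"),
    )
    nb_mean: float = 5.0
    nb_alpha: float = 0.1
    footprint_peak: str = "peak_promoter"
    footprint_interval: tuple = (120, 180)  # offsets within the peak
    footprint_log2fc_per_allele: float = -0.5

    # plants for the loss-of-function screens
    outlier_plants: tuple = (("TBK1", 0), ("NEK1", 1))
    outlier_plant_iqr: float = 4.0
    junction_plants: tuple = (("chr12:64845000-64846200", 0, 25),)
    junction_variant_offset: int = 40  # bp inside the intron from the 5' site
    n_background_junctions: int = 20
    ase_plants: tuple = (2,)  # sample slots with fully imbalanced allele reads
    ase_gene: str = "SETX"
    ase_n_sites: int = 4
    ase_reads_per_site: int = 30

    n_null_genes: int = 24
    seed: int = 0

    def __post_init__(self):
        f = np.asarray(self.founder_freqs, dtype=float)
        if (f < 0).any() or abs(f.sum() - 1) > 1e-9:
            raise ValueError("founder frequencies must be non-negative and sum to 1")
        # lognormal mean of non-carrier survival in months
        s = self.survival_noise_sd * math.log(10)
        m = 10 ** self.survival_baseline_log10 * math.exp(s**2 / 2)
        g0 = math.log10(1 + self.hre_month_deficit_code0 / m)
        g3 = math.log10(1 + self.hre_month_deficit_code3 / m)
        self.survival_hre_effect = g0
        self.survival_code_effect = (g3 - g0) / 3

    @property
    def mean_noncarrier_survival(self) -> float:
        s = self.survival_noise_sd * math.log(10)
        return 10 ** self.survival_baseline_log10 * math.exp(s**2 / 2)


def default_params(seed: int = 0) -> GeneratorParams:
    """Defaults matching the study's marginal allele frequencies and slopes.

    Founder frequencies solve: f(A,G,C) = 0.41 (rs2492816-A marginal),
    f(G,A,C) + f(G,A,G) = 0.22 (rs13691-A marginal), f(G,A,G) = 0.011
    (rs113860022-G marginal), with the (A, A, ·) haplotype frequency zero.
    """
    return GeneratorParams(seed=seed)


@dataclass
class SimulatedCohort:
    """Generated tables plus the truth of every planted effect."""

    samples: pd.DataFrame  # sample, status, hre_carrier, hap1, hap2, subgroup_code
    genotypes: dict  # sample -> GenotypeTriple
    clinical: pd.DataFrame
    visits: pd.DataFrame
    expression: pd.DataFrame  # genes x samples
    junctions: pd.DataFrame  # junction x samples
    allele_counts: pd.DataFrame
    variants: pd.DataFrame  # rare-variant table (sample, chrom, pos)
    peaks: pd.DataFrame
    cuts: pd.DataFrame  # read 5' ends, pre-shift (sample, chrom, pos, strand)
    truth: dict


def _alt_dose(pair, snp):
    return sum(a == SNP_ALLELES[snp][1] for a in pair)


def simulate_cohort(
    params: GeneratorParams, n_cases: int, n_controls: int
) -> SimulatedCohort:
    """Draw a full synthetic cohort; identical params give identical output."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("sample counts must be positive")
    rng = np.random.default_rng(params.seed)
    freqs = np.asarray(params.founder_freqs, dtype=float)

    n = n_cases + n_controls
    sample_ids = [f"CASE{i:04d}" for i in range(n_cases)] + [
        f"CTRL{i:04d}" for i in range(n_controls)
    ]
    status = ["case"] * n_cases + ["control"] * n_controls
    hre = np.concatenate(
        [rng.random(n_cases) < params.hre_prevalence, np.zeros(n_controls, bool)]
    )

    hap_idx1 = rng.choice(len(FOUNDERS), size=n, p=freqs)
    hap_idx2 = rng.choice(len(FOUNDERS), size=n, p=freqs)
    hap1 = [HRE_HAPLOTYPE if hre[i] else FOUNDERS[hap_idx1[i]] for i in range(n)]
    hap2 = [FOUNDERS[hap_idx2[i]] for i in range(n)]
    codes = [
        FOUNDER_CODES[hap2[i]] if hre[i] else np.nan for i in range(n)
    ]

    genotypes = {}
    doses = np.zeros((n, 3), dtype=int)
    for i, smp in enumerate(sample_ids):
        pairs = [tuple(sorted((hap1[i][k], hap2[i][k]))) for k in range(3)]
        genotypes[smp] = GenotypeTriple(*pairs)
        doses[i] = [_alt_dose(pairs[k], SNP_IDS[k]) for k in range(3)]

    samples = pd.DataFrame(
        {
            "sample": sample_ids,
            "status": status,
            "hre_carrier": hre,
            "hap1": ["".join(h) for h in hap1],
            "hap2": ["".join(h) for h in hap2],
            "subgroup_code": codes,
            "sex": rng.choice(["M", "F"], size=n),
            "frip": np.round(rng.uniform(0.2, 0.6, size=n), 4),
        }
    )

    # --- expression -------------------------------------------------------
    eff = np.asarray(params.expression_effects)
    c9_expr = (
        params.expression_baseline
        + doses @ eff
        + params.hre_expression_shift * hre
        + rng.normal(0, params.expression_noise_sd, n)
    )
    gene_names = ["C9orf72", *DEFAULT_CANDIDATE_GENES] + [
        f"NULLG{i:03d}" for i in range(params.n_null_genes)
    ]
    expr = pd.DataFrame(index=gene_names, columns=sample_ids, dtype=float)
    expr.loc["C9orf72"] = c9_expr
    for g in gene_names[1:]:
        base = rng.normal(10, 2)
        expr.loc[g] = base + rng.normal(0, 1, n)
    planted_outliers = []
    for gene, slot in params.outlier_plants:
        smp = sample_ids[slot]
        vals = expr.loc[gene].astype(float)
        med = float(np.median(vals))
        iqr = float(np.percentile(vals, 75) - np.percentile(vals, 25))
        expr.loc[gene, smp] = med - params.outlier_plant_iqr * iqr
        planted_outliers.append((gene, smp))

    # --- survival & clinical ---------------------------------------------
    log_surv = params.survival_baseline_log10 + rng.normal(
        0, params.survival_noise_sd, n
    )
    for i in range(n):
        if hre[i]:
            log_surv[i] += (
                params.survival_hre_effect
                + params.survival_code_effect * codes[i]
            )
    survival = 10**log_surv
    onset_site = rng.choice(["limb", "bulbar", "respiratory"], size=n, p=[0.6, 0.3, 0.1])
    clinical = pd.DataFrame(
        {
            "sample": sample_ids,
            "status": status,
            "hre_carrier": hre.astype(int),
            "survival_months": [
                round(float(survival[i]), 4) if status[i] == "case" else np.nan
                for i in range(n)
            ],
            "onset_site": [onset_site[i] if status[i] == "case" else "" for i in range(n)],
        }
    )

    # --- ALSFRS-R visits --------------------------------------------------
    visit_rows = []
    for i in range(n_cases):
        s_months = float(survival[i])
        t = params.visit_spacing_months
        while t < s_months:
            score = 48 * (1 - t / s_months) + rng.normal(0, params.alsfrs_noise_sd)
            visit_rows.append(
                {
                    "sample": sample_ids[i],
                    "months_from_onset": round(t, 4),
                    "alsfrs_total": float(np.clip(score, 0, 48)),
                    "death_month": round(s_months, 4),
                }
            )
            t += params.visit_spacing_months
        if t == params.visit_spacing_months:  # ensure at least one visit row
            visit_rows.append(
                {
                    "sample": sample_ids[i],
                    "months_from_onset": round(s_months / 2, 4),
                    "alsfrs_total": 24.0,
                    "death_month": round(s_months, 4),
                }
            )
    visits = pd.DataFrame(visit_rows)

    # --- Tn5 cut events ---------------------------------------------------
    peaks = pd.DataFrame(params.peaks, columns=["chrom", "start", "end", "peak_id"])
    cut_frames = []
    dose1 = doses[:, 0]  # rs2492816 alt dose drives the footprint
    for _, pk in peaks.iterrows():
        width = int(pk["end"] - pk["start"])
        mu = np.full((n, width), params.nb_mean)
        if pk["peak_id"] == params.footprint_peak:
            a, b = params.footprint_interval
            scale = 2.0 ** (params.footprint_log2fc_per_allele * dose1)
            mu[:, a:b] *= scale[:, None]
        lam = rng.gamma(1.0 / params.nb_alpha, mu * params.nb_alpha)
        counts = rng.poisson(lam)
        si, oi = np.nonzero(counts)
        reps = counts[si, oi]
        smp = np.repeat(np.asarray(sample_ids, dtype=object)[si], reps)
        cutpos = np.repeat(int(pk["start"]) + oi, reps)
        strand = np.where(rng.random(cutpos.size) < 0.5, "+", "-")
        read5 = np.where(strand == "+", cutpos - 5, cutpos + 4)
        cut_frames.append(
            pd.DataFrame(
                {"sample": smp, "chrom": pk["chrom"], "pos": read5, "strand": strand}
            )
        )
    cuts = (
        pd.concat(cut_frames, ignore_index=True)
        if cut_frames
        else pd.DataFrame(columns=["sample", "chrom", "pos", "strand"])
    )

    # --- splice junctions & rare variants ---------------------------------
    jidx = [
        f"chr12:{64_700_000 + 5000 * i}-{64_700_000 + 5000 * i + 1200}"
        for i in range(params.n_background_junctions)
    ]
    junctions = pd.DataFrame(
        rng.poisson(10, size=(params.n_background_junctions, n)),
        index=jidx,
        columns=sample_ids,
    )
    var_rows = []
    planted_junctions = []
    for jid, slot, count in params.junction_plants:
        row = pd.Series(0, index=sample_ids, name=jid)
        row[sample_ids[slot]] = count
        junctions = pd.concat([junctions, row.to_frame().T])
        chrom, span = jid.split(":")
        start = int(span.split("-")[0])
        var_rows.append(
            {
                "sample": sample_ids[slot],
                "chrom": chrom,
                "pos": start + params.junction_variant_offset,
            }
        )
        planted_junctions.append((jid, sample_ids[slot]))
    # a few common (non-unique) variants as background
    for k in range(3):
        for smp in sample_ids[: min(5, n)]:
            var_rows.append({"sample": smp, "chrom": "chr12", "pos": 64_000_000 + k})
    variants = pd.DataFrame(var_rows, columns=["sample", "chrom", "pos"])

    # --- allele counts (ASE) ----------------------------------------------
    ase_rows = []
    planted_ase = [sample_ids[slot] for slot in params.ase_plants]
    for smp in sample_ids:
        for site in range(params.ase_n_sites):
            if smp in planted_ase:
                ref = params.ase_reads_per_site
            else:
                ref = int(rng.binomial(params.ase_reads_per_site, 0.5))
            ase_rows.append(
                {
                    "sample": smp,
                    "gene": params.ase_gene,
                    "site": f"site{site}",
                    "ref_count": ref,
                    "alt_count": params.ase_reads_per_site - ref,
                }
            )
    allele_counts = pd.DataFrame(ase_rows)

    truth = {
        "founder_freqs": dict(zip(["".join(h) for h in FOUNDERS], freqs)),
        "expression_effects": dict(zip(SNP_IDS, params.expression_effects)),
        "hre_expression_shift": params.hre_expression_shift,
        "survival_code_effect_log10": params.survival_code_effect,
        "survival_hre_effect_log10": params.survival_hre_effect,
        "hre_month_deficit_code0": params.hre_month_deficit_code0,
        "hre_month_deficit_code3": params.hre_month_deficit_code3,
        "footprint_interval": params.footprint_interval,
        "footprint_log2fc_per_allele": params.footprint_log2fc_per_allele,
        "planted_outliers": planted_outliers,
        "planted_junctions": planted_junctions,
        "planted_ase_samples": planted_ase,
    }
    return SimulatedCohort(
        samples=samples,
        genotypes=genotypes,
        clinical=clinical,
        visits=visits,
        expression=expr,
        junctions=junctions,
        allele_counts=allele_counts,
        variants=variants,
        peaks=peaks,
        cuts=cuts,
        truth=truth,
    )


def truth_report(cohort: SimulatedCohort) -> pd.DataFrame:
    """Planted parameters keyed to the estimator expected to recover them."""
    rows = []
    t = cohort.truth
    for hap, f in t["founder_freqs"].items():
        rows.append(("founder_freq_" + hap, f, "em_haplotype_frequencies"))
    for snp, e in t["expression_effects"].items():
        rows.append(("expression_effect_" + snp, e, "dosage_effect"))
    rows.append(("hre_expression_shift", t["hre_expression_shift"], "dosage_effect"))
    rows.append(
        ("survival_effect_per_code", t["survival_code_effect_log10"], "subgroup_survival_model")
    )
    rows.append(
        ("hre_month_deficit_code0", t["hre_month_deficit_code0"], "within_genotype_difference")
    )
    rows.append(
        ("hre_month_deficit_code3", t["hre_month_deficit_code3"], "within_genotype_difference")
    )
    rows.append(
        ("footprint_log2fc_per_allele", t["footprint_log2fc_per_allele"], "per_base_dose_test")
    )
    for gene, smp in t["planted_outliers"]:
        rows.append((f"outlier_{gene}_{smp}", np.nan, "iqr_outliers"))
    for jid, smp in t["planted_junctions"]:
        rows.append((f"unique_junction_{jid}_{smp}", np.nan, "unique_junctions"))
    for smp in t["planted_ase_samples"]:
        rows.append((f"ase_imbalance_{smp}", np.nan, "allele_balance"))
    return pd.DataFrame(rows, columns=["parameter", "value", "estimator"])


# ---------------------------------------------------------------------------
# writers — same dialects the io module reads
# ---------------------------------------------------------------------------

def write_cohort(cohort: SimulatedCohort, outdir) -> dict:
    """Write the cohort in the pipeline's native file formats; returns the
    path of every file written."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    vcf = out / "genotypes.vcf"
    _write_vcf(cohort, vcf)
    paths["genotypes"] = vcf

    for name, df, kwargs in [
        ("clinical", cohort.clinical, {"index": False}),
        ("visits", cohort.visits, {"index": False}),
        ("expression", cohort.expression, {"index_label": "gene"}),
        ("junctions", cohort.junctions, {"index_label": "junction"}),
        ("allele_counts", cohort.allele_counts, {"index": False}),
        ("variants", cohort.variants, {"index": False}),
        ("samples", cohort.samples, {"index": False}),
        ("covariates", cohort.samples[["sample", "sex", "frip"]], {"index": False}),
    ]:
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", **kwargs)
        paths[name] = p

    peaks_bed = out / "peaks.bed"
    cohort.peaks[["chrom", "start", "end", "peak_id"]].to_csv(
        peaks_bed, sep="\t", header=False, index=False
    )
    paths["peaks"] = peaks_bed

    cuts_bed = out / "cuts.bed"
    bed = cohort.cuts.assign(
        start=cohort.cuts["pos"], end=cohort.cuts["pos"] + 1, score=0
    )[["chrom", "start", "end", "sample", "score", "strand"]]
    bed.to_csv(cuts_bed, sep="\t", header=False, index=False)
    paths["cuts"] = cuts_bed

    truth_p = out / "truth.tsv"
    truth_report(cohort).to_csv(truth_p, sep="\t", index=False)
    paths["truth"] = truth_p
    return paths


def _write_vcf(cohort: SimulatedCohort, path) -> None:
    sample_ids = list(cohort.samples["sample"])
    records = sorted(SNP_IDS, key=lambda s: SNP_POSITIONS[s])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={CHROM},length=138394717>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for snp in records:
            ref, alt = SNP_ALLELES[snp]
            gts = []
            for smp in sample_ids:
                pair = getattr(cohort.genotypes[smp], snp)
                if pair is None:
                    gts.append("./.")
                else:
                    d = sum(a == alt for a in pair)
                    gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[d])
            fh.write(
                f"{CHROM}\t{SNP_POSITIONS[snp]}\t{snp}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
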
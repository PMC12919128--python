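"""Rare loss-of-function screens.

Three rule-based screens replace manual inspection of candidate ALS genes:

* severe expression downregulation — samples more than ``k`` interquartile
  ranges below a gene's cohort median (default k = 3);
* allele-specific expression imbalance — pooled ref/alt read counts at
  heterozygous sites tested against a balanced binomial;
* carrier-unique splice junctions — junctions supported in exactly one
  sample and absent (below a noise floor) everywhere else, joined to rare
  variants carried uniquely by that sample near either splice site.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy.stats import binomtest

logger = logging.getLogger(__name__)


def iqr_outliers(
    expression: pd.DataFrame,
    genes: Sequence[str],
    k: float = 3.0,
) -> pd.DataFrame:
    """Robust low-expression scores for candidate genes.

    For each gene the score is (value − median) / IQR across samples; a
    sample is flagged when its score falls below −k.  Genes absent from the
    matrix or with zero IQR are skipped with a warning.
    """
    present = [g for g in genes if g in expression.index]
    for g in set(genes) - set(present):
        logger.warning("candidate gene %s absent from expression matrix", g)
    if not present:
        return pd.DataFrame(columns=["gene", "sample", "score", "flagged"])
    sub = expression.loc[present].astype(float)
    if sub.shape[1] < 8:
        raise ValueError("need at least 8 samples per gene")
    med = sub.median(axis=1)
    iqr = sub.quantile(0.75, axis=1) - sub.quantile(0.25, axis=1)
    zero = iqr == 0
    for g in sub.index[zero]:
        logger.warning("gene %s has zero IQR; skipped", g)
    sub = sub[~zero]
    scores = sub.sub(med[~zero], axis=0).div(iqr[~zero], axis=0)
    out = (
        scores.rename_axis("gene")
        .reset_index()
        .melt(id_vars="gene", var_name="sample", value_name="score")
    )
    out["flagged"] = out["score"] < -k
    return out[["gene", "sample", "score", "flagged"]]


@dataclass
class ASERecord:
    """Pooled allele-balance summary for one sample × gene."""

    sample: str
    gene: str
    ref_reads: int
    alt_reads: int
    fraction_ref: float
    p: float
    n_sites: int


def allele_balance(
    sample: str, gene: str, site_counts: Sequence[tuple]
) -> ASERecord:
    """Pool ref/alt read counts across heterozygous sites and test the
    pooled ref fraction against 0.5 with a two-sided exact binomial test."""
    ref = int(sum(r for r, _ in site_counts))
    alt = int(sum(a for _, a in site_counts))
    total = ref + alt
    if total == 0:
        raise ValueError("zero total reads across sites")
    res = binomtest(ref, total, 0.5, alternative="two-sided")
    return ASERecord(
        sample=sample,
        gene=gene,
        ref_reads=ref,
        alt_reads=alt,
        fraction_ref=ref / total,
        p=float(res.pvalue),
        n_sites=len(site_counts),
    )


def rank_allele_balance(records: Sequence[ASERecord]) -> pd.DataFrame:
    """Rank samples by imbalance: |fraction − 0.5| descending, then p."""
    df = pd.DataFrame(
        [
            {"sample": r.sample, "gene": r.gene, "ref": r.ref_reads,
             "alt": r.alt_reads, "fraction_ref": r.fraction_ref, "p": r.p,
             "n_sites": r.n_sites}
            for r in records
        ]
    )
    if df.empty:
        return df
    df["imbalance"] = (df["fraction_ref"] - 0.5).abs()
    return (
        df.sort_values(["imbalance", "p"], ascending=[False, True])
        .reset_index(drop=True)
    )


def _parse_junction(jid: str):
    m = re.match(r"(\w+):(\d+)-(\d+)", str(jid))
    if not m:
        return None
    return m.group(1), int(m.group(2)), int(m.group(3))


def unique_junctions(
    junctions: pd.DataFrame,
    min_count: int = 5,
    noise_count: int = 2,
    variants: Optional[pd.DataFrame] = None,
    window: int = 100,
) -> pd.DataFrame:
    """Flag junctions supported in exactly one sample.

    A junction is flagged when its count is ≥ ``min_count`` in exactly one
    sample and < ``noise_count`` in every other sample (the noise floor
    tolerates stray mismapped reads).  When a rare-variant table
    (``sample, chrom, pos``) is supplied, each flagged junction is joined to
    variants carried uniquely by the carrier sample within ``window`` bp of
    either splice site.
    """
    if not min_count > noise_count >= 0:
        raise ValueError("require min_count > noise_count >= 0")
    rows = []
    uniq_var = None
    if variants is not None and len(variants):
        counts = variants.groupby(["chrom", "pos"])["sample"].nunique()
        solo = counts[counts == 1].index
        uniq_var = variants.set_index(["chrom", "pos"]).loc[solo].reset_index()
    for jid, cnts in junctions.iterrows():
        cnts = cnts.astype(float)
        carriers = cnts[cnts >= min_count]
        if len(carriers) != 1:
            continue
        carrier = carriers.index[0]
        if (cnts.drop(carrier) >= noise_count).any():
            continue
        linked = ""
        parsed = _parse_junction(jid)
        if uniq_var is not None and parsed is not None:
            chrom, start, end = parsed
            near = uniq_var[
                (uniq_var["sample"] == carrier)
                & (uniq_var["chrom"] == chrom)
                & (
                    ((uniq_var["pos"] - start).abs() <= window)
                    | ((uniq_var["pos"] - end).abs() <= window)
                )
            ]
            linked = ";".join(
                f"{r.chrom}:{r.pos}" for r in near.itertuples()
            )
        rows.append(
            {"junction": jid, "carrier": carrier,
             "count": float(cnts[carrier]), "linked_variants": linked}
        )
    return pd.DataFrame(rows, columns=["junction", "carrier", "count", "linked_variants"])
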
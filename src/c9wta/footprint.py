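"""Single-basepair Tn5 footprinting.

ATAC-seq insertion sites are recovered from read 5' ends with the standard
+5 (plus strand) / −4 (minus strand) shift, tabulated per base and sample
inside each peak of interest, and summarised two ways:

* genotype-aggregated cut-frequency profiles (each sample normalised by its
  total cuts in the peak, then averaged within genotype), and
* a per-base negative-binomial regression of raw counts on alt-allele dose
  with covariates, median-of-ratios size factors and Benjamini–Hochberg
  adjustment across bases — a protein footprint shows up as a run of bases
  whose cut counts depend on genotype.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

LOG2 = np.log(2.0)

#: emphasis threshold used when flagging top hits (reported, never filtered on)
TOP_HIT_ADJ_P = 1e-40


@dataclass
class BaseBySampleMatrix:
    """Per-base cut counts: rows (peak, offset) × sample columns."""

    counts: pd.DataFrame  # MultiIndex rows (peak, offset)
    peak_totals: pd.DataFrame  # peak × sample totals

    @property
    def samples(self):
        return list(self.counts.columns)


def shift_cuts(reads: pd.DataFrame) -> pd.DataFrame:
    """Convert read 5' ends to Tn5 insertion coordinates.

    ``reads`` needs columns ``sample, chrom, pos, strand`` with 0-based
    positions; plus-strand reads shift +5, minus-strand −4.
    """
    strands = set(reads["strand"].unique())
    if not strands <= {"+", "-"}:
        raise ValueError(f"unknown strand value(s): {strands - {'+', '-'}}")
    out = reads.copy()
    out["pos"] = out["pos"] + np.where(out["strand"] == "+", 5, -4)
    return out


def _merge_peaks(peaks: pd.DataFrame) -> pd.DataFrame:
    merged = []
    for chrom, grp in peaks.sort_values(["chrom", "start"]).groupby("chrom"):
        cur = None
        for _, row in grp.iterrows():
            if cur is None or row["start"] >= cur["end"]:
                if cur is not None:
                    merged.append(cur)
                cur = row[["chrom", "start", "end", "peak_id"]].to_dict()
            else:
                logger.warning("merging overlapping peaks on %s", chrom)
                cur["end"] = max(cur["end"], row["end"])
        if cur is not None:
            merged.append(cur)
    return pd.DataFrame(merged)


def tabulate_cuts(
    cuts: pd.DataFrame,
    peaks: pd.DataFrame,
    samples: Optional[Sequence[str]] = None,
) -> BaseBySampleMatrix:
    """Count Tn5 insertions per (peak, basepair offset, sample).

    Peaks are 0-based half-open; cuts on the end coordinate fall outside.
    Overlapping peaks are merged with a warning.  Cuts outside all peaks are
    dropped.  Every offset of every peak gets a row, zero-filled.
    """
    peaks = _merge_peaks(peaks)
    if samples is None:
        samples = sorted(cuts["sample"].unique())
    samples = list(samples)
    blocks, totals = [], []
    for _, pk in peaks.iterrows():
        width = int(pk["end"] - pk["start"])
        sel = cuts[
            (cuts["chrom"] == pk["chrom"])
            & (cuts["pos"] >= pk["start"])
            & (cuts["pos"] < pk["end"])
        ]
        if len(sel):
            pivot = (
                sel.assign(offset=(sel["pos"] - pk["start"]).astype(int))
                .groupby(["offset", "sample"])
                .size()
                .unstack(fill_value=0)
            )
            mat = pivot.reindex(
                index=range(width), columns=samples, fill_value=0
            ).fillna(0).astype(int)
        else:
            mat = pd.DataFrame(0, index=range(width), columns=samples, dtype=int)
        mat.index = pd.MultiIndex.from_product(
            [[pk["peak_id"]], range(width)], names=["peak", "offset"]
        )
        blocks.append(mat)
        totals.append(mat.sum(axis=0).rename(pk["peak_id"]))
    counts = pd.concat(blocks) if blocks else pd.DataFrame(columns=samples)
    peak_totals = pd.DataFrame(totals) if totals else pd.DataFrame(columns=samples)
    return BaseBySampleMatrix(counts=counts, peak_totals=peak_totals)


def genotype_profiles(
    matrix: BaseBySampleMatrix,
    dose: Mapping[str, int],
    peak_id,
) -> pd.DataFrame:
    """Per-genotype normalised cut-frequency profile over one peak.

    Each sample's base counts are divided by its total cuts in the peak
    (so each sample's profile sums to 1), then averaged within genotype.
    Zero-total samples are excluded with a warning.
    """
    sub = matrix.counts.loc[peak_id]
    totals = matrix.peak_totals.loc[peak_id]
    cols = {}
    usable = {}
    for smp in sub.columns:
        if smp not in dose:
            continue
        if totals[smp] == 0:
            logger.warning("sample %s has zero cuts in peak %s; excluded", smp, peak_id)
            continue
        usable.setdefault(dose[smp], []).append(sub[smp] / totals[smp])
    if not usable:
        raise ValueError(f"no sample with non-zero cut total in peak {peak_id}")
    for g, profs in sorted(usable.items()):
        cols[g] = pd.concat(profs, axis=1).mean(axis=1)
    return pd.DataFrame(cols)


def stack_and_filter(matrices: Sequence[BaseBySampleMatrix]) -> BaseBySampleMatrix:
    """Stack per-peak matrices row-wise and drop rows averaging < 1 count
    per sample (strictly less; a mean of exactly 1 is kept)."""
    sample_sets = {tuple(m.samples) for m in matrices}
    if len(sample_sets) != 1:
        raise ValueError("matrices have differing sample sets")
    counts = pd.concat([m.counts for m in matrices])
    totals = pd.concat([m.peak_totals for m in matrices])
    keep = counts.mean(axis=1) >= 1.0
    n_removed = int((~keep).sum())
    logger.info("stack_and_filter: removed %d low-count rows of %d", n_removed, len(counts))
    return BaseBySampleMatrix(counts=counts[keep], peak_totals=totals)


def _size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over the retained rows."""
    logc = np.log(counts.where(counts > 0))
    log_geo = logc.mean(axis=1)
    ok = np.isfinite(log_geo) & counts.gt(0).all(axis=1)
    if not ok.any():
        return pd.Series(1.0, index=counts.columns)
    ratios = np.log(counts[ok]).sub(log_geo[ok], axis=0)
    sf = np.exp(ratios.median(axis=0))
    return sf / np.exp(np.log(sf).mean())


def _fit_base(y, X, offset):
    """NB GLM with method-of-moments dispersion (floored); returns
    (beta_dose, se, p) on the natural-log scale."""
    mu0 = np.mean(y / np.exp(offset))
    norm = y / np.exp(offset)
    var = np.var(norm, ddof=1)
    alpha = max((var - mu0) / mu0**2 if mu0 > 0 else 0.0, 1e-8)
    model = sm.GLM(
        y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(maxiter=100)
    return fit.params["dose"], fit.bse["dose"], fit.pvalues["dose"]


def per_base_dose_test(
    matrix: BaseBySampleMatrix,
    dose: Mapping[str, int],
    covariates: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Negative-binomial Wald test of genotype dose on per-base cut counts.

    Returns one row per retained base with the log2 fold change per alt
    allele, its SE, raw and BH-adjusted p-values and a ``top_hit`` flag at
    the stringent adj-p emphasis threshold.  Bases whose fit fails are
    recorded with missing statistics.
    """
    samples = matrix.samples
    d = pd.Series({s: dose[s] for s in samples}, dtype=float)
    if d.nunique() < 2:
        raise ValueError("dose is constant across samples")
    X = pd.DataFrame({"dose": d})
    if covariates is not None:
        cov = covariates.loc[samples]
        if cov.isna().any().any():
            raise ValueError("covariates contain missing values")
        X = pd.concat([X, cov], axis=1)
    X = sm.add_constant(X)
    sf = _size_factors(matrix.counts)
    offset = np.log(sf[samples]).to_numpy()

    rows = []
    for idx, row in matrix.counts.iterrows():
        y = row.to_numpy(dtype=float)
        try:
            beta, se, p = _fit_base(y, X, offset)
            if not (np.isfinite(beta) and np.isfinite(se) and np.isfinite(p)):
                raise FloatingPointError
            rows.append(
                {"peak": idx[0], "offset": idx[1], "log2fc": beta / LOG2,
                 "se": se / LOG2, "p": p}
            )
        except Exception:
            rows.append(
                {"peak": idx[0], "offset": idx[1], "log2fc": np.nan,
                 "se": np.nan, "p": np.nan}
            )
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["adj_p"] = np.nan
    if ok.any():
        out.loc[ok, "adj_p"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["top_hit"] = out["adj_p"] < TOP_HIT_ADJ_P
    return out
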
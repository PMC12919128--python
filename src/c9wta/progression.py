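"""Survival statistics for the WTA-subgroup modifier analysis.

Disease duration in expansion carriers is regressed, on the log10 scale, on
the ordinal WTA subgroup code after symmetric trimming of the survival
extremes; carrier-vs-non-carrier differences within a shared genotype are
quantified with Welch's t-test on the month scale.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .config import EffectEstimate


def trim_extremes(values: Sequence[float], frac: float) -> np.ndarray:
    """Indices retained after removing the ``ceil(frac*n)`` largest and
    smallest values, agnostic of any grouping.

    Ties at a trim boundary are broken by original position: among equal
    values the lower index is removed first (stable sort order).
    """
    if not 0 <= frac < 0.5:
        raise ValueError("trim fraction must lie in [0, 0.5)")
    values = np.asarray(values, dtype=float)
    n = values.size
    if frac == 0:
        return np.arange(n)
    k = math.ceil(frac * n)
    low = np.argsort(values, kind="stable")[:k]
    high = np.argsort(-values, kind="stable")[:k]
    removed = set(low.tolist()) | set(high.tolist())
    kept = np.array([i for i in range(n) if i not in removed], dtype=int)
    if kept.size < 3:
        raise ValueError(f"only {kept.size} values remain after trimming")
    return kept


def subgroup_survival_model(records: pd.DataFrame) -> EffectEstimate:
    """OLS of log10(survival months) on the integer WTA subgroup code.

    ``records`` needs columns ``survival_months`` (> 0, already trimmed) and
    ``subgroup_code``.  Returns the per-code slope in log10-months.
    """
    surv = np.asarray(records["survival_months"], dtype=float)
    code = np.asarray(records["subgroup_code"], dtype=float)
    if np.any(surv <= 0):
        raise ValueError("survival months must be positive")
    if len(np.unique(code)) < 2:
        raise ValueError("need at least two distinct subgroup codes")
    y = np.log10(surv)
    if np.allclose(y, y[0]):
        # degenerate: no variance in outcome
        return EffectEstimate(0.0, 0.0, 1.0, len(y), transform="log10")
    X = sm.add_constant(code)
    fit = sm.OLS(y, X).fit()
    return EffectEstimate(
        estimate=float(fit.params[1]),
        se=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
        n=len(y),
        transform="log10",
    )


def within_genotype_difference(
    c9: Sequence[float], non_c9: Sequence[float]
) -> EffectEstimate:
    """mean(carrier) − mean(non-carrier) survival in months, Welch SE and
    two-sided p, for patients sharing a WTA genotype."""
    c9 = np.asarray(c9, dtype=float)
    non_c9 = np.asarray(non_c9, dtype=float)
    if c9.size < 2 or non_c9.size < 2:
        raise ValueError("each group needs at least 2 observations")
    diff = float(c9.mean() - non_c9.mean())
    se = float(
        np.sqrt(c9.var(ddof=1) / c9.size + non_c9.var(ddof=1) / non_c9.size)
    )
    if se == 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        p = float(st.ttest_ind(c9, non_c9, equal_var=False).pvalue)
    return EffectEstimate(estimate=diff, se=se, p=p, n=int(c9.size + non_c9.size))


def genotype_difference_table(
    clinical: pd.DataFrame,
    genotype_col: str = "wta_label",
    carrier_col: str = "hre_carrier",
    survival_col: str = "survival_months",
) -> pd.DataFrame:
    """Per-genotype carrier-vs-non-carrier survival difference table."""
    rows = []
    for label, grp in clinical.groupby(genotype_col, sort=True):
        c9 = grp.loc[grp[carrier_col].astype(bool), survival_col].to_numpy(float)
        non = grp.loc[~grp[carrier_col].astype(bool), survival_col].to_numpy(float)
        if c9.size < 2 or non.size < 2:
            continue
        eff = within_genotype_difference(c9, non)
        rows.append(
            {
                "genotype": label,
                "n_c9": c9.size,
                "n_non_c9": non.size,
                "difference_months": eff.estimate,
                "se": eff.se,
                "p": eff.p,
            }
        )
    return pd.DataFrame(rows)


def negative_control_model(
    clinical: pd.DataFrame,
    dose_col: str = "diplotype_dose",
    survival_col: str = "survival_months",
) -> Optional[EffectEstimate]:
    """The subgroup model re-run on non-carriers' diplotype dosage; expected
    null (no genotype-dependent survival trend outside expansion carriers)."""
    df = clinical.dropna(subset=[dose_col, survival_col])
    if df[dose_col].nunique() < 2 or len(df) < 3:
        return None
    renamed = df.rename(columns={dose_col: "subgroup_code"})
    renamed = renamed[[survival_col, "subgroup_code"]].rename(
        columns={survival_col: "survival_months"}
    )
    return subgroup_survival_model(renamed)
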
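"""ALSFRS-R time-to-threshold statistics.

The revised ALS Functional Rating Scale total (0–48) declines over the
disease course.  Rather than the noisy per-visit slope, progression is
summarised by the interpolated time from onset to a score threshold:
each patient's trajectory is anchored at 48 at onset and 0 at death (when
known), and the first downward crossing of the threshold is read off the
piecewise-linear interpolant.  The primary threshold is 24 — half the
maximum — with a robustness scan over thresholds 3..45.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .progression import trim_extremes

logger = logging.getLogger(__name__)

SCAN_RANGE = (3, 45)


@dataclass
class VisitSeries:
    """Anchored, time-sorted ALSFRS-R series for one patient."""

    patient_id: str
    times: np.ndarray  # months from onset
    scores: np.ndarray  # ALSFRS-R total
    death_month: Optional[float] = None


def build_anchored_series(
    patient_id: str,
    visits: Sequence[tuple],
    death_month: Optional[float] = None,
) -> VisitSeries:
    """Anchor a raw visit list at (0, 48) and, when death is known, at
    (death_month, 0); sort by time and average duplicate timestamps."""
    pts = [(0.0, 48.0)]
    for t, s in visits:
        if t < 0:
            raise ValueError(f"visit at negative time {t} for {patient_id}")
        if not 0 <= s <= 48:
            raise ValueError(f"score {s} outside [0, 48] for {patient_id}")
        pts.append((float(t), float(s)))
    if death_month is not None:
        if death_month < 0:
            raise ValueError("death month must be non-negative")
        pts.append((float(death_month), 0.0))
    df = pd.DataFrame(pts, columns=["t", "s"]).groupby("t", sort=True).mean()
    return VisitSeries(
        patient_id=patient_id,
        times=df.index.to_numpy(float),
        scores=df["s"].to_numpy(float),
        death_month=death_month,
    )


def time_to_threshold(series: VisitSeries, i: float) -> Optional[float]:
    """Months from onset to the first downward crossing of score ``i`` on
    the piecewise-linear trajectory; an exact hit at a visit returns that
    visit's time; ``None`` when the trajectory never reaches ``i``."""
    t, s = series.times, series.scores
    for k in range(len(t)):
        if s[k] == i:
            return float(t[k])
        if k > 0 and s[k - 1] > i > s[k]:
            slope = (s[k] - s[k - 1]) / (t[k] - t[k - 1])
            return float(t[k - 1] + (i - s[k - 1]) / slope)
    return None


def threshold_table(
    patients: Sequence[VisitSeries], i: float, trim_frac: float = 0.05
) -> pd.DataFrame:
    """Per-patient time to threshold ``i``; undefined times dropped, then the
    extremes trimmed agnostic of any grouping."""
    rows = [
        (p.patient_id, tt)
        for p in patients
        if (tt := time_to_threshold(p, i)) is not None
    ]
    if len(rows) < 3:
        raise ValueError(f"fewer than 3 patients reach threshold {i}")
    df = pd.DataFrame(rows, columns=["patient_id", "t_months"])
    kept = trim_extremes(df["t_months"].to_numpy(), trim_frac)
    return df.iloc[kept].reset_index(drop=True)


def _validate_thresholds(thresholds, lo=0, hi=48):
    for i in thresholds:
        if not lo <= i <= hi:
            raise ValueError(f"threshold {i} outside [{lo}, {hi}]")


def group_trajectories(
    groups: Mapping, thresholds: Sequence[float], trim_frac: float = 0.05
) -> pd.DataFrame:
    """Mean ± SE time-to-threshold per (group, threshold).

    ``groups`` maps a group label (e.g. subgroup code) to its patients'
    VisitSeries.  Trimming at each threshold is applied across all groups
    jointly; groups left with fewer than 2 defined times are omitted with a
    warning.
    """
    _validate_thresholds(thresholds)
    rows = []
    for i in thresholds:
        flat, labels = [], []
        for label, patients in groups.items():
            for p in patients:
                tt = time_to_threshold(p, i)
                if tt is not None:
                    flat.append(tt)
                    labels.append(label)
        if len(flat) < 3:
            continue
        try:
            kept = trim_extremes(np.asarray(flat), trim_frac)
        except ValueError:
            logger.warning("threshold %s skipped: too few times after trimming", i)
            continue
        kept_t = np.asarray(flat)[kept]
        kept_lab = np.asarray(labels, dtype=object)[kept]
        for label in groups:
            vals = kept_t[kept_lab == label]
            if vals.size < 2:
                logger.warning(
                    "group %r omitted at threshold %s (n=%d)", label, i, vals.size
                )
                continue
            rows.append(
                {
                    "group": label,
                    "threshold": i,
                    "mean_months": float(vals.mean()),
                    "se_months": float(vals.std(ddof=1) / np.sqrt(vals.size)),
                    "n": int(vals.size),
                }
            )
    return pd.DataFrame(rows)


def threshold_scan(
    groups: Mapping, i_range: Sequence[int] = range(3, 46), trim_frac: float = 0.05
) -> pd.DataFrame:
    """Per-threshold linear association of time-to-threshold with group code.

    At each threshold in 3..45 the retained times are regressed on the
    numeric group code; degenerate thresholds are recorded with missing
    statistics.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    _validate_thresholds(i_range, *SCAN_RANGE)
    rows = []
    for i in i_range:
        flat, codes = [], []
        for label, patients in groups.items():
            for p in patients:
                tt = time_to_threshold(p, i)
                if tt is not None:
                    flat.append(tt)
                    codes.append(float(label))
        slope = se = p_val = np.nan
        n = 0
        if len(flat) >= 3:
            try:
                kept = trim_extremes(np.asarray(flat), trim_frac)
            except ValueError:
                kept = np.array([], dtype=int)
            t_arr = np.asarray(flat)[kept]
            c_arr = np.asarray(codes)[kept]
            n = t_arr.size
            if n >= 3 and np.unique(c_arr).size >= 2 and not np.allclose(t_arr, t_arr[0] if n else 0):
                res = st.linregress(c_arr, t_arr)
                slope, se, p_val = res.slope, res.stderr, res.pvalue
        rows.append({"threshold": i, "slope": slope, "se": se, "p": p_val, "n": n})
    return pd.DataFrame(rows)
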
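"""Descriptive and rank-based statistics for distances and deviations.

Box summaries follow the Tukey convention with whiskers clipped to the
observed range: upper whisker = min(max x, Q3 + 1.5 IQR), lower whisker =
max(min x, Q1 - 1.5 IQR).  Quartiles use linear interpolation between
order statistics (type 7), the default of mainstream statistical
environments; an alternative convention can be passed through.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class BoxSummary:
    n: int
    median: float
    q1: float
    q3: float
    mean: float
    whisker_low: float
    whisker_high: float


@dataclass(frozen=True)
class KWResult:
    """Kruskal-Wallis rank test result (tie-corrected H, df = k - 1)."""

    H: float
    df: int
    p_value: float
    tie_corrected: bool


def box_summary(values: Sequence[float], method: str = "linear") -> BoxSummary:
    """Five-number-style summary with 1.5*IQR whiskers clipped to the data."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("box_summary: empty input")
    if not np.all(np.isfinite(v)):
        raise ValueError("box_summary: non-finite values")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method=method)
    iqr = abs(q3 - q1)
    return BoxSummary(
        n=int(v.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        mean=float(v.mean()),
        whisker_low=float(max(v.min(), q1 - 1.5 * iqr)),
        whisker_high=float(min(v.max(), q3 + 1.5 * iqr)),
    )


def kruskal_wallis(values: Sequence[float], group_labels: Sequence) -> KWResult:
    """Kruskal-Wallis H with mid-ranks and tie correction.

    H = [12 / (N(N+1))] * sum_j R_j^2 / n_j - 3(N+1) on mid-ranks, divided
    by the tie-correction factor 1 - sum(t^3 - t) / (N^3 - N).  With all
    observations identical H is defined as 0.  The p-value is the upper
    chi-square tail at k-1 degrees of freedom (reported, not exact under
    heavy ties at tiny n).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(group_labels)
    if v.size != g.size:
        raise ValueError("values and group_labels differ in length")
    labels = pd.unique(g)
    if len(labels) < 2:
        raise ValueError("kruskal_wallis: need at least 2 groups")
    counts = pd.Series(g).value_counts()
    if (counts == 0).any():
        raise ValueError("kruskal_wallis: empty group")
    n = v.size
    ranks = sps.rankdata(v)  # mid-ranks
    h = 0.0
    for lab in labels:
        r = ranks[g == lab]
        h += r.sum() ** 2 / r.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction
    _, t = np.unique(v, return_counts=True)
    denom = 1.0 - float(((t**3 - t).sum()) / (n**3 - n))
    tie_corrected = bool(np.any(t > 1))
    if denom == 0.0:
        h = 0.0  # every observation identical
    else:
        h = h / denom
    df = len(labels) - 1
    p = float(sps.chi2.sf(max(h, 0.0), df))
    return KWResult(H=float(max(h, 0.0)), df=df, p_value=p, tie_corrected=tie_corrected)


def deviation_summary_table(deviation_records: pd.DataFrame) -> pd.DataFrame:
    """Per-interval box summaries of deviation percentages.

    Input is the long table from :func:`trackthin.resample.deviation_table`
    (columns ``interval_min`` and ``deviation_pct``); output has one row
    per interval, sorted ascending.
    """
    rows = []
    for interval, grp in deviation_records.groupby("interval_min", sort=True):
        b = box_summary(grp["deviation_pct"].to_numpy())
        rows.append(
            {
                "interval_min": interval,
                "n": b.n,
                "median": b.median,
                "q1": b.q1,
                "q3": b.q3,
                "mean": b.mean,
                "whisker_low": b.whisker_low,
                "whisker_high": b.whisker_high,
            }
        )
    return pd.DataFrame(rows)
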
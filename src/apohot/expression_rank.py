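"""Housekeeping-normalised percentile expression ranks and group tests.

Each gene's expression per sample is divided by the housekeeping anchor
(GAPDH by default), the per-gene median of these relative values is
taken across samples, and genes are ranked on a percentile scale in
(0, 1] with average ranks for ties.  The anchor normalisation cancels
any sample-wise positive rescaling of the matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix


def gapdh_percentile_rank(
    expr: ExpressionMatrix,
    anchor: str = "GAPDH",
    labels: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Percentile rank table of median anchor-relative expression.

    Returns a DataFrame indexed by gene with columns ``median_rel``
    (median of gene/anchor across samples), ``rank`` (percentile in
    (0, 1], average ranks for ties) and ``label`` (oncogene / TSG /
    unknown, from ``labels`` when given).
    """
    values = expr.values
    if anchor not in values.index:
        raise ValueError(f"anchor gene {anchor!r} absent from matrix")
    anchor_row = values.loc[anchor]
    if (anchor_row <= 0).any():
        raise ValueError(f"anchor gene {anchor!r} must be positive in every sample")
    if values.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    rel = values.div(anchor_row, axis=1)
    median_rel = rel.median(axis=1)
    ranks = pd.Series(
        stats.rankdata(median_rel.to_numpy(), method="average") / len(median_rel),
        index=median_rel.index,
        name="rank",
    )
    table = pd.DataFrame({"median_rel": median_rel, "rank": ranks})
    if labels is not None:
        lab = pd.Series(labels)
        table["label"] = lab.reindex(table.index).fillna("unknown")
    else:
        table["label"] = "unknown"
    return table


def expression_group_test(
    group_a,
    group_b,
    alternative: str = "two-sided",
    allow_overlap: bool = False,
) -> tuple[float, float]:
    """Wilcoxon rank-sum comparison of two value groups.

    Groups may be pandas Series (overlapping indices raise unless
    ``allow_overlap``) or plain arrays.  Returns (statistic, p).
    """
    if isinstance(group_a, pd.Series) and isinstance(group_b, pd.Series):
        overlap = group_a.index.intersection(group_b.index)
        if len(overlap) and not allow_overlap:
            raise ValueError(f"groups overlap on {len(overlap)} items")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    stat, p = stats.mannwhitneyu(a, b, alternative=alternative)
    return float(stat), float(p)


def quartile_bins(rank_table: pd.DataFrame) -> pd.Series:
    """Quartile presentation of the percentile ranks (1 = bottom)."""
    return pd.Series(
        np.minimum(np.ceil(rank_table["rank"] * 4).astype(int), 4),
        index=rank_table.index,
        name="quartile",
    )
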
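"""MS-MLPA group statistics: site filters and the Friedman + Dunn comparison.

Input is a CpG-site x group table of mean methylation fractions (the assay
reports one mean per site and condition).  The analysis drops sites at 0%
methylation in every group, eliminates sites with missing group values, and
compares groups by a Friedman test on within-site ranks followed by Dunn's
multiple-comparison post hoc.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["validate_table", "zero_filter", "drop_missing_sites",
           "friedman_dunn"]


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a site x group methylation-fraction table (values in [0,1] or NaN)."""
    if table.empty:
        raise ValueError("empty MS-MLPA table")
    if table.columns.duplicated().any():
        raise ValueError("duplicate group labels")
    vals = table.to_numpy(dtype=float)
    finite = vals[~np.isnan(vals)]
    if finite.size and ((finite < 0).any() or (finite > 1).any()):
        raise ValueError("methylation fractions must lie in [0, 1]")
    return table


def zero_filter(table: pd.DataFrame) -> pd.DataFrame:
    """Drop sites whose methylation is exactly 0 in every group."""
    validate_table(table)
    all_zero = table.eq(0).all(axis=1)
    kept = table.loc[~all_zero]
    logger.info("zero_filter retained %d of %d sites", len(kept), len(table))
    return kept


def drop_missing_sites(table: pd.DataFrame) -> pd.DataFrame:
    """Drop sites with any missing group value."""
    validate_table(table)
    kept = table.dropna(axis=0)
    logger.info("drop_missing_sites retained %d of %d sites",
                len(kept), len(table))
    return kept


def _friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from an n x k within-block rank table."""
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    numer = (k - 1) * float(np.sum(col_sums ** 2) - n ** 2 * k * (k + 1) ** 2 / 4)
    denom = float(np.sum(ranks ** 2) - n * k * (k + 1) ** 2 / 4)
    if denom == 0.0:  # every block fully tied: no rank variation at all
        return 0.0
    return numer / denom


def friedman_dunn(table: pd.DataFrame, adjust: str = "bonferroni"):
    """Friedman test across groups with Dunn's pairwise post hoc.

    Sites are the blocks, groups the treatments; values are ranked within
    each site with average ranks for ties and the standard tie correction
    in the chi-square statistic.  Dunn's z for a pair is the difference of
    mean ranks over sqrt(k(k+1)/(6n)); pairwise p values are two-sided
    normal tails adjusted by Bonferroni (or Holm) over all k(k-1)/2 pairs.

    Returns (statistic, p, pairwise) where pairwise is a DataFrame with
    columns group_i, group_j, z, p, p_adjusted.
    """
    validate_table(table)
    if table.isna().any().any():
        raise ValueError("incomplete blocks: call drop_missing_sites first")
    n, k = table.shape
    if k < 3:
        raise ValueError("need >= 3 groups for the Friedman test")
    if n < 2:
        raise ValueError("need >= 2 complete sites (blocks)")
    if adjust not in {"bonferroni", "holm"}:
        raise ValueError("adjust must be 'bonferroni' or 'holm'")

    ranks = np.vstack([stats.rankdata(row) for row in table.to_numpy(float)])
    statistic = _friedman_statistic(ranks)
    p = float(stats.chi2.sf(statistic, k - 1)) if statistic > 0 else 1.0

    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    pairs = list(itertools.combinations(range(k), 2))
    rows = []
    for i, j in pairs:
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_ij = 2.0 * float(stats.norm.sf(abs(z)))
        rows.append([table.columns[i], table.columns[j], z, p_ij])
    pairwise = pd.DataFrame(rows, columns=["group_i", "group_j", "z", "p"])
    if adjust == "bonferroni":
        pairwise["p_adjusted"] = np.minimum(1.0, pairwise["p"] * len(pairs))
    else:
        order = np.argsort(pairwise["p"].to_numpy())
        adj = np.empty(len(pairs))
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (len(pairs) - rank) * pairwise["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        pairwise["p_adjusted"] = adj
    return statistic, p, pairwise
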
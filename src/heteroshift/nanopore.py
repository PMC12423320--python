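"""Nanopore methylation summarization and allele-count heteroplasmy.

Per-read modification calls carry a log-likelihood ratio (LLR) whose sign
says whether a cytosine looks modified.  Reads are thresholded into per-site
modified/unmodified counts, converted to a log-methyl ratio

    LMR = ln((modified + c) / (unmodified + c))        (pseudocount c = 1)

and mapped to a probability-like methylation level by the logistic sigmoid
P = 1/(1 + e^-LMR), which for this definition equals the smoothed count
fraction (modified + c)/(modified + unmodified + 2c).  Site probabilities
are aggregated to per-chromosome medians (the mitochondrial chromosome is
always reported, separately trackable) and conditions are compared with the
Wilcoxon matched-pairs signed-rank test over chromosomes.  Heteroplasmy of
an mtDNA point mutation is the mutant base fraction of the pileup at that
position, A/(A+G) for the m.13513 G>A site.
"""

from __future__ import annotations

import logging
from collections import namedtuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["site_counts_from_reads", "lmr_and_prob", "sites_from_bedmethyl",
           "chromosome_summaries", "paired_wilcoxon", "allele_heteroplasmy"]

SiteCountResult = namedtuple("SiteCountResult", ["sites", "n_ambiguous"])
WilcoxonResult = namedtuple("WilcoxonResult", ["statistic", "p_value",
                                               "n_pairs", "degenerate"])


def site_counts_from_reads(calls: pd.DataFrame,
                           llr_cutoff: float = 0.0) -> SiteCountResult:
    """Threshold per-read LLR calls into per-site modified/unmodified counts.

    ``calls`` needs columns chromosome, position, llr.  A read is modified
    when llr > cutoff, unmodified when llr < -cutoff; reads inside the
    ambiguous band |llr| <= cutoff are discarded and tallied.
    """
    required = {"chromosome", "position", "llr"}
    if not required.issubset(calls.columns):
        raise ValueError(f"calls need columns {sorted(required)}")
    llr = calls["llr"].to_numpy(dtype=float)
    if not np.isfinite(llr).all():
        raise ValueError("non-finite LLR")
    mod = llr > llr_cutoff
    unmod = llr < -llr_cutoff
    n_ambiguous = int((~mod & ~unmod).sum())
    if n_ambiguous:
        logger.info("discarded %d ambiguous reads (|llr| <= %g)",
                    n_ambiguous, llr_cutoff)
    grouped = (pd.DataFrame({
        "chromosome": calls["chromosome"], "position": calls["position"],
        "modified_count": mod.astype(int), "unmodified_count": unmod.astype(int)})
        .groupby(["chromosome", "position"], as_index=False).sum())
    return SiteCountResult(sites=grouped, n_ambiguous=n_ambiguous)


def lmr_and_prob(sites: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Add lmr and prob columns to a per-site count table.

    With pseudocount c, lmr = ln((modified+c)/(unmodified+c)) and the
    sigmoid of lmr reduces to (modified+c)/(modified+unmodified+2c).  With
    c = 0 a zero count saturates prob to exactly 0 or 1; saturated sites
    are flagged with a warning.
    """
    m = sites["modified_count"].to_numpy(dtype=float)
    u = sites["unmodified_count"].to_numpy(dtype=float)
    if pseudocount <= 0 and ((m + u) == 0).any():
        raise ValueError("zero-coverage site with zero pseudocount")
    with np.errstate(divide="ignore"):
        lmr = np.log(m + pseudocount) - np.log(u + pseudocount)
    prob = 1.0 / (1.0 + np.exp(-lmr))
    saturated = np.isinf(lmr)
    if saturated.any():
        prob[saturated] = (lmr[saturated] > 0).astype(float)
        logger.warning("%d sites with saturated LMR (prob exactly 0 or 1)",
                       int(saturated.sum()))
    out = sites.copy()
    out["lmr"] = lmr
    out["prob"] = prob
    return out


def sites_from_bedmethyl(records) -> pd.DataFrame:
    """Per-site count table from :class:`heteroshift.io.SiteCounts` records."""
    return pd.DataFrame({
        "chromosome": [r.chromosome for r in records],
        "position": [r.position for r in records],
        "modified_count": [r.modified_count for r in records],
        "unmodified_count": [r.unmodified_count for r in records],
    })


def chromosome_summaries(sites: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Median site methylation probability per chromosome.

    The mitochondrial chromosome (chrM) is reported like the rest but can be
    singled out downstream; an input without chrM simply lacks that row.
    """
    if "prob" not in sites.columns:
        raise ValueError("run lmr_and_prob first")
    grouped = sites.groupby("chromosome")["prob"]
    out = pd.DataFrame({
        "median_prob": grouped.median(),
        "n_sites": grouped.size(),
    }).reset_index()
    out["condition"] = condition
    return out


def paired_wilcoxon(summaries_a: pd.DataFrame, summaries_b: pd.DataFrame,
                    alternative: str = "two-sided") -> WilcoxonResult:
    """Wilcoxon matched-pairs signed-rank test of per-chromosome medians.

    Chromosomes are matched between the two conditions (mismatched sets are
    an error).  Zero differences are dropped per the Wilcoxon convention;
    if every difference is zero the comparison is degenerate and p = 1 by
    convention.  The p value is exact for <= 25 informative pairs, normal
    approximation beyond.
    """
    a = summaries_a.set_index("chromosome")["median_prob"]
    b = summaries_b.set_index("chromosome")["median_prob"]
    if set(a.index) != set(b.index):
        raise ValueError("chromosome sets differ between conditions")
    b = b.reindex(a.index)
    d = (a - b).to_numpy(dtype=float)
    nonzero = d[d != 0]
    if nonzero.size == 0:
        logger.warning("all paired differences are zero; degenerate comparison")
        return WilcoxonResult(0.0, 1.0, 0, True)
    method = "exact" if nonzero.size <= 25 else "approx"
    res = stats.wilcoxon(nonzero, alternative=alternative, method=method)
    return WilcoxonResult(float(res.statistic), float(res.pvalue),
                          int(nonzero.size), False)


def allele_heteroplasmy(counts: dict, mutant_base: str = "A",
                        wildtype_base: str = "G") -> float:
    """Mutant-allele fraction from base counts at one mtDNA position.

    Returns counts[mut] / (counts[mut] + counts[wt]); other bases are
    ignored but logged as a fraction of total depth.
    """
    for base, c in counts.items():
        if c < 0:
            raise ValueError(f"negative count for base {base}")
    mut = counts.get(mutant_base, 0)
    wt = counts.get(wildtype_base, 0)
    if mut + wt == 0:
        raise ValueError(
            f"zero combined depth for {mutant_base}/{wildtype_base}")
    other = sum(counts.values()) - mut - wt
    if other:
        logger.info("%d reads (%.1f%% of depth) on other bases ignored",
                    other, 100.0 * other / sum(counts.values()))
    return mut / (mut + wt)
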
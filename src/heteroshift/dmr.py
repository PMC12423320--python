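"""Differential methylation calling with the consecutive-CpG run rule.

The caller works on Illumina-style beta values.  For each CpG probe it
computes the group difference

    delta = mean(beta, test group) - mean(beta, control group)

and a one-tailed unpaired Student's t test in the direction of the observed
delta.  A probe is directionally significant when |delta| clears the
configured threshold (0.2 by default; presets carry the 0.4 and 0.27
variants used for mutant-vs-wild-type and high-vs-low comparisons) and
p < alpha.  A differentially methylated region (DMR) is then a maximal run
of >= 2 probes that are *consecutive in genomic manifest order* on one
chromosome and significant in the same direction — an intervening manifest
probe that is excluded, missing or non-significant breaks the run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io import BetaMatrix, ConfigError

logger = logging.getLogger(__name__)

__all__ = [
    "DmrConfig",
    "PRESETS",
    "DmrRun",
    "beta_from_intensities",
    "probe_deltas",
    "call_dmr_runs",
    "dmr_gene_list",
    "enrichment_test",
]


@dataclass(frozen=True)
class DmrConfig:
    """Thresholds and options for the DMR caller.

    hyper_threshold / hypo_threshold
        minimum delta for a hyper- (>= 0.2) or hypomethylated (<= -0.2) call.
    alpha
        significance level for the one-tailed t test (0.05).
    min_run
        minimum number of consecutive same-direction probes per region (2).
    min_obs_per_group
        probes with fewer non-missing observations in either group are
        excluded, not silently dropped (2).
    max_gap_bp
        optional cap on the genomic gap between adjacent run members;
        None (default) leaves runs unbounded in span.
    t_variant
        "pooled" (classical Student) or "welch".
    two_tailed / fdr
        optional deviations from the default raw one-tailed regime.
    """

    hyper_threshold: float = 0.2
    hypo_threshold: float = -0.2
    alpha: float = 0.05
    min_run: int = 2
    min_obs_per_group: int = 2
    max_gap_bp: int | None = None
    t_variant: str = "pooled"
    two_tailed: bool = False
    fdr: bool = False

    def __post_init__(self):
        if not (self.hypo_threshold < 0 < self.hyper_threshold):
            raise ValueError("need hypo_threshold < 0 < hyper_threshold")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if self.t_variant not in {"pooled", "welch"}:
            raise ValueError("t_variant must be 'pooled' or 'welch'")


#: Named threshold presets: the 0.2 default plus the stricter 0.4
#: (mutant vs wild-type) and 0.27 (high vs low heteroplasmy) variants.
PRESETS = {
    "methods": DmrConfig(),
    "fig3c-mutwt": DmrConfig(hyper_threshold=0.4, hypo_threshold=-0.4),
    "fig3c-highlow": DmrConfig(hyper_threshold=0.27, hypo_threshold=-0.27),
}


@dataclass(frozen=True)
class DmrRun:
    """A maximal run of >= 2 consecutive same-direction significant probes."""

    chromosome: str
    start_pos: int  # 1-based inclusive
    end_pos: int    # 1-based inclusive
    probe_ids: tuple
    direction: str  # hyper | hypo
    mean_delta: float
    gene_labels: frozenset = frozenset()

    def __post_init__(self):
        if len(self.probe_ids) < 1:
            raise ValueError("empty run")
        if self.direction not in {"hyper", "hypo"}:
            raise ValueError(f"bad direction {self.direction!r}")


def beta_from_intensities(M: float, U: float) -> float:
    """Beta value from methylated/unmethylated fluorescence intensities.

    beta = max(M, 0) / (|U| + |M| + 100); the +100 offset regularizes
    low-intensity probes, so the result is always in [0, 1).
    """
    if not (math.isfinite(M) and math.isfinite(U)):
        raise ValueError("intensities must be finite")
    return max(M, 0.0) / (abs(U) + abs(M) + 100.0)


def _one_tailed_p(t: float, df: float, delta: float) -> float:
    # one-tailed in the direction of the observed delta
    if delta > 0:
        return float(stats.t.sf(t, df))
    if delta < 0:
        return float(stats.t.cdf(t, df))
    return 1.0


def probe_deltas(matrix: BetaMatrix, test_group: str, control_group: str,
                 config: DmrConfig = DmrConfig()) -> pd.DataFrame:
    """Per-probe delta, one-tailed p and direction for one group comparison.

    Returns a DataFrame indexed by probe id with columns delta, p_value,
    direction (hyper/hypo/none), n_test, n_control, excluded.  Probes with
    fewer than ``min_obs_per_group`` non-missing values in either group are
    flagged excluded with delta/p set to NaN.
    """
    test_samples = matrix.samples_in_group(test_group)
    ctrl_samples = matrix.samples_in_group(control_group)
    if set(test_samples) & set(ctrl_samples):
        raise ConfigError("test and control groups overlap")

    tv = matrix.values[test_samples].to_numpy(dtype=float)
    cv = matrix.values[ctrl_samples].to_numpy(dtype=float)
    n_t = (~np.isnan(tv)).sum(axis=1)
    n_c = (~np.isnan(cv)).sum(axis=1)
    excluded = (n_t < config.min_obs_per_group) | (n_c < config.min_obs_per_group)

    with np.errstate(invalid="ignore"):
        mean_t = np.nanmean(np.where(np.isnan(tv), np.nan, tv), axis=1)
        mean_c = np.nanmean(np.where(np.isnan(cv), np.nan, cv), axis=1)
        var_t = _nanvar_ddof1(tv)
        var_c = _nanvar_ddof1(cv)

    delta = mean_t - mean_c
    n_probes = len(matrix.probes)
    p = np.ones(n_probes)
    direction = np.array(["none"] * n_probes, dtype=object)

    for i in range(n_probes):
        if excluded[i]:
            continue
        d = delta[i]
        if config.t_variant == "pooled":
            dfree = n_t[i] + n_c[i] - 2
            sp2 = (((n_t[i] - 1) * var_t[i] + (n_c[i] - 1) * var_c[i])
                   / dfree) if dfree > 0 else 0.0
            se = math.sqrt(sp2 * (1.0 / n_t[i] + 1.0 / n_c[i]))
        else:
            a, b = var_t[i] / n_t[i], var_c[i] / n_c[i]
            se = math.sqrt(a + b)
            dfree = ((a + b) ** 2 / (a ** 2 / (n_t[i] - 1) + b ** 2 / (n_c[i] - 1))
                     if a + b > 0 else n_t[i] + n_c[i] - 2)
        if se == 0.0:
            # zero variance in both groups: certain difference or none at all
            p[i] = 0.0 if d != 0 else 1.0
        else:
            t = d / se
            p[i] = (_one_tailed_p(t, dfree, d) if not config.two_tailed
                    else 2 * float(stats.t.sf(abs(t), dfree)))

    p_eff = p.copy()
    if config.fdr:
        from statsmodels.stats.multitest import multipletests
        ok = ~excluded
        if ok.any():
            p_eff[ok] = multipletests(p[ok], method="fdr_bh")[1]

    sig = (~excluded) & (p_eff < config.alpha)
    direction[sig & (delta >= config.hyper_threshold)] = "hyper"
    direction[sig & (delta <= config.hypo_threshold)] = "hypo"

    out = pd.DataFrame({
        "delta": np.where(excluded, np.nan, delta),
        "p_value": np.where(excluded, np.nan, p_eff),
        "direction": direction,
        "n_test": n_t,
        "n_control": n_c,
        "excluded": excluded,
    }, index=pd.Index(matrix.probes, name="probe_id"))
    logger.info("probe_deltas %s vs %s: %d probes, %d excluded, %d significant",
                test_group, control_group, n_probes, int(excluded.sum()),
                int((direction != "none").sum()))
    return out


def _nanvar_ddof1(x: np.ndarray) -> np.ndarray:
    n = (~np.isnan(x)).sum(axis=1)
    out = np.zeros(x.shape[0])
    ok = n > 1
    if ok.any():
        with np.errstate(invalid="ignore"):
            v = np.nanvar(x[ok], axis=1, ddof=1)
        out[ok] = v
    return out


def call_dmr_runs(deltas: pd.DataFrame, manifest: pd.DataFrame,
                  config: DmrConfig = DmrConfig()) -> list:
    """Call maximal consecutive same-direction runs along the manifest.

    Probes are traversed in the manifest's genomic order per chromosome; a
    run collects adjacent probes sharing a non-"none" direction.  Probes
    that are excluded, untested or absent from ``deltas`` break runs, and
    runs never span chromosomes (nor gaps > ``max_gap_bp`` when set).
    """
    unknown = set(deltas.index) - set(manifest["probe_id"])
    if unknown:
        raise ValueError(f"probe absent from manifest: {sorted(unknown)[0]!r}")

    dir_map = deltas["direction"].to_dict()
    delta_map = deltas["delta"].to_dict()
    runs: list = []
    current: list = []  # (probe_id, position, delta, genes)
    cur_dir = None
    cur_chrom = None
    last_pos = None

    def flush():
        nonlocal current
        if len(current) >= config.min_run:
            probes = tuple(p for p, _, _, _ in current)
            genes = frozenset().union(*(g for _, _, _, g in current))
            runs.append(DmrRun(
                chromosome=cur_chrom,
                start_pos=current[0][1], end_pos=current[-1][1],
                probe_ids=probes, direction=cur_dir,
                mean_delta=float(np.mean([d for _, _, d, _ in current])),
                gene_labels=genes))
        current = []

    for row in manifest.itertuples(index=False):
        d = dir_map.get(row.probe_id, "none")
        broke_chrom = row.chromosome != cur_chrom
        gap_broken = (config.max_gap_bp is not None and last_pos is not None
                      and not broke_chrom
                      and row.position - last_pos > config.max_gap_bp)
        if d in ("hyper", "hypo"):
            if broke_chrom or gap_broken or d != cur_dir:
                flush()
                cur_dir = d
            cur_chrom = row.chromosome
            current.append((row.probe_id, int(row.position),
                            delta_map[row.probe_id], row.gene_labels))
        else:
            flush()
            cur_dir = None
            cur_chrom = row.chromosome
        last_pos = int(row.position)
    flush()
    logger.info("called %d runs (min_run=%d)", len(runs), config.min_run)
    return runs


def dmr_gene_list(runs) -> pd.DataFrame:
    """Collapse runs to a unique gene table (gene, direction, n_probes).

    Every member probe of a run supports each of the run's gene labels in
    the run's direction; a gene supported by both directions gets the
    majority direction, ties are reported as "mixed".
    """
    counts: dict = {}
    for r in runs:
        for gene in r.gene_labels:
            c = counts.setdefault(gene, {"hyper": 0, "hypo": 0})
            c[r.direction] += len(r.probe_ids)
    rows = []
    for gene in sorted(counts):
        c = counts[gene]
        if c["hyper"] > c["hypo"]:
            direction, n = "hyper", c["hyper"]
        elif c["hypo"] > c["hyper"]:
            direction, n = "hypo", c["hypo"]
        else:
            direction, n = "mixed", c["hyper"] + c["hypo"]
        rows.append((gene, direction, n))
    return pd.DataFrame(rows, columns=["gene", "direction", "n_probes"])


def enrichment_test(gene_list, annotation_set, universe_size: int):
    """Hypergeometric upper-tail over-representation test.

    Probability of observing at least the measured overlap between
    ``gene_list`` and ``annotation_set`` when drawing |gene_list| genes
    from a universe of ``universe_size``.
    """
    genes = set(gene_list)
    annot = set(annotation_set)
    if universe_size < len(genes | annot):
        raise ValueError("universe smaller than the union of the two sets")
    overlap = len(genes & annot)
    p = float(stats.hypergeom.sf(overlap - 1, universe_size,
                                 len(annot), len(genes)))
    return overlap, min(1.0, p)
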
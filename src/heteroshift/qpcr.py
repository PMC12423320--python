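"""ddCT-style heteroplasmy and mtDNA-content estimation from qPCR CT values.

The assay runs three amplicons per sample: one specific to the mutant mtDNA
allele (mut), one amplifying both mutant and wild-type molecules (all), and
a nuclear reference gene (ref, B2M).  Assuming perfect doubling per cycle,

    heteroplasmy  = 2^-(mutCT - allCT)
    mtDNA content = 2^-(allCT - refCT)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["CtMeasurement", "HeteroplasmyEstimate", "heteroplasmy_dct",
           "mtdna_content", "heteroplasmy_shift", "read_ct_table"]


@dataclass(frozen=True)
class CtMeasurement:
    """CT triple for one sample; refCT (nuclear gene) may be absent."""

    sample_id: str
    mutCT: float | None = None
    allCT: float | None = None
    refCT: float | None = None

    def __post_init__(self):
        for name in ("mutCT", "allCT", "refCT"):
            v = getattr(self, name)
            if v is not None and not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")


@dataclass(frozen=True)
class HeteroplasmyEstimate:
    sample_id: str
    raw: float       # 2^-dCT, may exceed 1 under plate noise
    clamped: float   # min(raw, 1)


def heteroplasmy_dct(m: CtMeasurement, efficiency: float = 1.0) -> HeteroplasmyEstimate:
    """Heteroplasmy fraction from the mut/all CT difference.

    raw = (1 + efficiency)^-(mutCT - allCT); the default efficiency of 1
    gives the classical base-2 formula.  Values above 1 (mut amplicon
    crossing threshold before the all amplicon) are clamped with a warning
    — plate noise can produce a slightly negative dCT at high heteroplasmy.
    """
    if m.mutCT is None or m.allCT is None:
        raise ValueError(f"sample {m.sample_id}: mutCT and allCT required")
    raw = (1.0 + efficiency) ** (-(m.mutCT - m.allCT))
    if raw > 1.0:
        logger.warning("sample %s: heteroplasmy estimate %.3f > 1, clamped",
                       m.sample_id, raw)
    return HeteroplasmyEstimate(m.sample_id, raw=raw, clamped=min(raw, 1.0))


def mtdna_content(m: CtMeasurement, efficiency: float = 1.0) -> float:
    """Relative mtDNA copy number: the all amplicon normalized to the nuclear gene."""
    if m.allCT is None or m.refCT is None:
        raise ValueError(f"sample {m.sample_id}: allCT and refCT required")
    return (1.0 + efficiency) ** (-(m.allCT - m.refCT))


def heteroplasmy_shift(before: HeteroplasmyEstimate,
                       after: HeteroplasmyEstimate) -> float:
    """Change in mutant load in percentage points; negative means reduction."""
    return 100.0 * (after.clamped - before.clamped)


def read_ct_table(source) -> list:
    """Read a tidy CT table (sample, target, ct) into CtMeasurement triples.

    ``source`` is a path (TSV/CSV by extension) or a DataFrame.  Targets are
    named mut / all / ref; replicate rows for one (sample, target) are
    averaged on the CT scale before the ddCT formulas are applied.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        sep = "," if str(source).lower().endswith(".csv") else "\t"
        df = pd.read_csv(source, sep=sep)
    required = {"sample", "target", "ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"CT table needs columns {sorted(required)}")
    bad = set(df["target"]) - {"mut", "all", "ref"}
    if bad:
        raise ValueError(f"unknown targets {sorted(bad)}; use mut/all/ref")
    means = df.groupby(["sample", "target"])["ct"].mean().unstack()
    out = []
    for sample, row in means.iterrows():
        out.append(CtMeasurement(
            sample_id=str(sample),
            mutCT=None if pd.isna(row.get("mut")) else float(row["mut"]),
            allCT=None if pd.isna(row.get("all")) else float(row["all"]),
            refCT=None if pd.isna(row.get("ref")) else float(row["ref"])))
    logger.info("read %d CT triples from %d rows", len(out), len(df))
    return out
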
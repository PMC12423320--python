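"""Readers and writers for the tabular formats the pipeline touches.

All genomic positions are stored 1-based internally; the bedMethyl reader
converts from 0-based half-open intervals on the way in.  Chromosome names
are normalized to UCSC "chr"-prefixed form ("MT" becomes "chrM") so that
manifests and nanopore tables mixing conventions line up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "RowError",
    "ConfigError",
    "ProbeAnnotation",
    "BetaMatrix",
    "SiteCounts",
    "normalize_chromosome",
    "chromosome_sort_key",
    "read_manifest",
    "write_manifest",
    "manifest_from_frame",
    "read_design",
    "read_beta_matrix",
    "read_bedmethyl",
    "combine_mod_codes",
    "write_bed6_runs",
]


class FormatError(ValueError):
    """A file is missing a mandatory column or is otherwise malformed."""


class RowError(ValueError):
    """A single record could not be parsed; the message names the line."""


class ConfigError(ValueError):
    """Inconsistent configuration, e.g. a sample absent from the design."""


# --------------------------------------------------------------------------
# chromosome naming and ordering

def normalize_chromosome(name: str) -> str:
    """Map a chromosome label to UCSC convention: "1"->"chr1", "MT"->"chrM"."""
    s = str(name).strip()
    if not s:
        raise ValueError("empty chromosome name")
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() in {"MT", "M"}:
        s = "M"
    return "chr" + s


def chromosome_sort_key(chrom: str) -> tuple:
    """Sort key giving chr1..chr22 numerically, then chrX, chrY, chrM, others."""
    body = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if body.isdigit():
        return (0, int(body), "")
    special = {"X": 0, "Y": 1, "M": 2}
    if body.upper() in special:
        return (1, special[body.upper()], "")
    return (2, 0, body)


# --------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class ProbeAnnotation:
    """One manifest row: where a probe sits in the genome and which genes it tags."""

    probe_id: str
    chromosome: str
    position: int  # 1-based
    gene_labels: frozenset = frozenset()
    strand: str = "unknown"

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"probe {self.probe_id}: position must be >= 1")
        if not self.chromosome:
            raise ValueError(f"probe {self.probe_id}: empty chromosome")


@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions plus the sample design.

    ``values`` is a DataFrame (index: probe ids, columns: sample ids) with
    entries in [0, 1] or NaN for missing.  ``design`` is indexed by sample id
    with columns ``mutation_type`` (WT / mut13 / mut8 ...), ``load``
    (none / low / high) and optionally ``heteroplasmy_fraction`` and ``group``.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self):
        vals = self.values.to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        if finite.size and ((finite < 0).any() or (finite > 1).any()):
            raise ValueError("beta values must lie in [0, 1]")
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ConfigError(
                f"samples missing from design: {sorted(missing)}")

    @property
    def probes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    def samples_in_group(self, label: str) -> list:
        """Samples matching *label* against the design.

        A label is resolved, in order, against an explicit ``group`` column,
        ``mutation_type``, and ``load``; the special label ``mut`` selects
        every non-wild-type sample.
        """
        d = self.design
        if "group" in d.columns and (d["group"] == label).any():
            return list(d.index[d["group"] == label])
        if (d["mutation_type"] == label).any():
            return list(d.index[d["mutation_type"] == label])
        if (d["load"] == label).any():
            return list(d.index[d["load"] == label])
        if label == "mut":
            return list(d.index[~d["mutation_type"].isin(["WT", "wt"])])
        raise ConfigError(f"group label {label!r} matches no samples in design")


@dataclass(frozen=True)
class SiteCounts:
    """Per-site modified/unmodified read counts from a bedMethyl record."""

    chromosome: str
    position: int  # 1-based
    modified_count: int
    unmodified_count: int
    mod_code: str = "m"
    strand: str = "."

    def __post_init__(self):
        if self.modified_count < 0 or self.unmodified_count < 0:
            raise ValueError("counts must be non-negative")


# --------------------------------------------------------------------------
# manifest

_PROBE_ALIASES = ("probe_id", "IlmnID", "Name", "probe")
_CHROM_ALIASES = ("chromosome", "CHR", "chrom", "chr")
_POS_ALIASES = ("position", "MAPINFO", "pos")
_GENE_ALIASES = ("gene_labels", "UCSC_RefGene_Name", "gene", "genes")
_STRAND_ALIASES = ("strand", "Strand")


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _find_column(columns, aliases, what, required=True):
    for a in aliases:
        if a in columns:
            return a
    if required:
        raise FormatError(f"missing mandatory column for {what}; "
                          f"expected one of {aliases}")
    return None


def manifest_from_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate, normalize and sort a raw manifest frame.

    Returns a DataFrame with columns probe_id, chromosome, position,
    gene_labels (frozenset), strand, sorted by (chromosome, position,
    probe_id) with the chromosome order of :func:`chromosome_sort_key`.
    """
    cols = df.columns
    pcol = _find_column(cols, _PROBE_ALIASES, "probe id")
    ccol = _find_column(cols, _CHROM_ALIASES, "chromosome")
    poscol = _find_column(cols, _POS_ALIASES, "position")
    gcol = _find_column(cols, _GENE_ALIASES, "gene labels", required=False)
    scol = _find_column(cols, _STRAND_ALIASES, "strand", required=False)

    out = pd.DataFrame({"probe_id": df[pcol].astype(str)})
    dup = out["probe_id"][out["probe_id"].duplicated()]
    if not dup.empty:
        raise FormatError(f"duplicated probe_id: {dup.iloc[0]!r}")
    out["chromosome"] = [normalize_chromosome(c) for c in df[ccol]]
    positions = []
    for i, raw in enumerate(df[poscol]):
        try:
            p = int(raw)
            if p < 1:
                raise ValueError
        except (TypeError, ValueError):
            raise RowError(f"line {i + 2}: unparseable position {raw!r}")
        positions.append(p)
    out["position"] = positions
    if gcol is not None:
        out["gene_labels"] = [
            frozenset(g for g in str(v).split(";") if g and g != "nan")
            if not pd.isna(v) else frozenset()
            for v in df[gcol]
        ]
    else:
        out["gene_labels"] = [frozenset()] * len(out)
    out["strand"] = df[scol].astype(str) if scol is not None else "unknown"

    key = out["chromosome"].map(chromosome_sort_key)
    out = (out.assign(_k=key)
              .sort_values(["_k", "position", "probe_id"], kind="mergesort")
              .drop(columns="_k")
              .reset_index(drop=True))
    return out


def read_manifest(path) -> pd.DataFrame:
    """Read a probe manifest (TSV/CSV by extension), sorted genomically."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    manifest = manifest_from_frame(df)
    logger.info("read %d manifest records from %s", len(manifest), path)
    return manifest


def write_manifest(manifest: pd.DataFrame, path) -> None:
    out = manifest.copy()
    out["gene_labels"] = [";".join(sorted(g)) for g in out["gene_labels"]]
    out.to_csv(path, sep=_sep_for(path), index=False)


def manifest_records(manifest: pd.DataFrame) -> list:
    """The manifest as a list of :class:`ProbeAnnotation`."""
    return [
        ProbeAnnotation(r.probe_id, r.chromosome, int(r.position),
                        frozenset(r.gene_labels), r.strand)
        for r in manifest.itertuples(index=False)
    ]


# --------------------------------------------------------------------------
# beta matrix

def read_design(path) -> pd.DataFrame:
    """Read a sample design table (sample_id, mutation_type, load, ...)."""
    df = pd.read_csv(path, sep=_sep_for(path))
    if "sample_id" not in df.columns:
        raise FormatError("design table needs a sample_id column")
    for col in ("mutation_type", "load"):
        if col not in df.columns:
            raise FormatError(f"design table needs a {col} column")
    return df.set_index("sample_id")


def read_beta_matrix(path, design: pd.DataFrame) -> BetaMatrix:
    """Read a probes x samples beta-value table and attach the design.

    The first column holds probe ids; empty cells become missing (NaN),
    never zero.  Values outside [0, 1] are rejected.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (TypeError, ValueError) as exc:
            raise RowError(f"non-numeric cell in sample column {col!r}: {exc}")
    bad = df[(df < 0) | (df > 1)].stack()
    if not bad.empty:
        probe, sample = bad.index[0]
        raise RowError(
            f"beta value out of [0,1] at probe {probe!r}, sample {sample!r}: "
            f"{bad.iloc[0]}")
    bm = BetaMatrix(values=df, design=design)
    logger.info("read beta matrix %d probes x %d samples from %s",
                len(bm.probes), len(bm.samples), path)
    return bm


def write_beta_matrix(bm: BetaMatrix, path) -> None:
    bm.values.to_csv(path, sep=_sep_for(path), index_label="probe_id")


# --------------------------------------------------------------------------
# bedMethyl

def read_bedmethyl(path) -> list:
    """Read a ModKit-dialect bedMethyl file into :class:`SiteCounts` records.

    Accepts the full 18-column ModKit layout (valid coverage in column 10,
    modified count in column 12) or a minimal 6-column layout
    (chrom, start, end, mod code, valid coverage, modified count).
    Separate 5mC ("m") and 5hmC ("h") rows for one site stay distinct;
    see :func:`combine_mod_codes`.
    """
    records = []
    rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise RowError(f"line {lineno}: expected >= 6 tab-separated "
                               f"columns, got {len(f)}")
            try:
                chrom = normalize_chromosome(f[0])
                start, end = int(f[1]), int(f[2])
                code = f[3]
                if len(f) >= 12:
                    strand = f[5]
                    coverage = int(f[9])
                    modified = int(f[11])
                else:
                    strand = "."
                    coverage = int(f[4])
                    modified = int(f[5])
            except ValueError:
                rejected += 1
                raise RowError(f"line {lineno}: unparseable bedMethyl record")
            if end != start + 1:
                raise RowError(f"line {lineno}: interval length must be 1 "
                               f"(got {start}-{end})")
            if modified < 0 or coverage < modified:
                raise RowError(f"line {lineno}: inconsistent counts "
                               f"(coverage {coverage}, modified {modified})")
            records.append(SiteCounts(
                chromosome=chrom, position=start + 1,
                modified_count=modified, unmodified_count=coverage - modified,
                mod_code=code, strand=strand))
    logger.info("read %d bedMethyl records from %s (%d rejected)",
                len(records), path, rejected)
    return records


def combine_mod_codes(sites) -> list:
    """Merge 5mC/5hmC rows at the same site into single "combined" records.

    The upstream basecaller calls both marks; a single per-site methylation
    measure adds the modified counts.  Rows for one site share the same valid
    coverage (each code's "unmodified" tally includes reads carrying the other
    mark), so combined unmodified = coverage - sum of modified.
    """
    by_site: dict = {}
    for s in sites:
        key = (s.chromosome, s.position, s.strand)
        by_site.setdefault(key, []).append(s)
    out = []
    for (chrom, pos, strand), group in by_site.items():
        if len(group) == 1:
            out.append(group[0])
        else:
            coverage = group[0].modified_count + group[0].unmodified_count
            total_mod = sum(g.modified_count for g in group)
            out.append(SiteCounts(
                chromosome=chrom, position=pos,
                modified_count=total_mod,
                unmodified_count=max(0, coverage - total_mod),
                mod_code="combined", strand=strand))
    out.sort(key=lambda s: (chromosome_sort_key(s.chromosome), s.position))
    return out


# --------------------------------------------------------------------------
# BED6 writer for DMR runs

def write_bed6_runs(runs, path) -> None:
    """Write DMR runs as BED6: name is the direction, score is 1000*|mean delta|."""
    with open(path, "w") as fh:
        for r in runs:
            score = int(min(1000, round(1000 * abs(r.mean_delta))))
            fh.write(f"{r.chromosome}\t{r.start_pos - 1}\t{r.end_pos}\t"
                     f"{r.direction}\t{score}\t.\n")
    logger.info("wrote %d runs to %s", len(list(runs)), path)
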
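"""Synthetic data with known ground truth for every pipeline stage.

The generators realize exactly the assumptions the analyses make: a
group-structured beta matrix with planted runs of consecutive
differentially methylated probes, CT triples drawn from the ddCT model,
per-read LLR calls from a two-component Gaussian around known site
methylation fractions, and binomial allele counts at a known heteroplasmy.
The study-like preset mirrors the study design: five groups (WT, 13L, 13H,
8L, 8H) of three samples, 2,000 probes over 23 nuclear chromosomes plus a
7-probe chrM, and planted runs that are 75% hypermethylated in the
high-load groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BetaMatrix

logger = logging.getLogger(__name__)

__all__ = ["EpicSimSpec", "CtSimSpec", "NanoporeSimSpec",
           "simulate_epic", "simulate_ct", "simulate_nanopore",
           "simulate_archetypes", "study_like_spec"]


@dataclass
class EpicSimSpec:
    """Parameters for a synthetic beta matrix.

    chromosomes: list of (name, n_probes); probes are spaced 1 kb apart.
    groups: sample_id -> (mutation_type, load); samples whose load is in
    ``affected_loads`` carry the planted deltas.
    planted_runs: list of (chromosome, start_index, length, delta) with the
    run direction given by the sign of delta; runs must not overlap.
    noise: truncated normal on the beta scale, clipped to [0.001, 0.999]
    (logit-normal by ``noise_model="logit"``).
    """

    chromosomes: list
    groups: dict
    planted_runs: list = field(default_factory=list)
    baseline_beta: float = 0.5
    noise_sd: float = 0.05
    missing_rate: float = 0.0
    affected_loads: frozenset = frozenset({"high"})
    noise_model: str = "truncnorm"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.baseline_beta < 1:
            raise ValueError("baseline_beta must be in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_model not in {"truncnorm", "logit"}:
            raise ValueError("noise_model must be 'truncnorm' or 'logit'")
        sizes = dict(self.chromosomes)
        occupied: dict = {}
        for chrom, start, length, delta in self.planted_runs:
            if chrom not in sizes:
                raise ValueError(f"planted run on unknown chromosome {chrom}")
            if length < 1 or start < 0 or start + length > sizes[chrom]:
                raise ValueError(f"planted run out of range on {chrom}")
            if delta == 0:
                raise ValueError("planted delta must be nonzero")
            span = occupied.setdefault(chrom, set())
            idx = set(range(start, start + length))
            if span & idx:
                raise ValueError(f"overlapping planted runs on {chrom}")
            span |= idx


@dataclass
class CtSimSpec:
    """CT triples under the ddCT model: allCT = base + noise and
    mutCT = base - log2(h_true) + noise, so E[2^-(mutCT-allCT)] ~ h_true."""

    h_true: float
    base_ct: float = 25.0
    noise_sd: float = 0.0
    replicates: int = 1
    ref_offset: float = -2.0  # refCT = base_ct + ref_offset + noise
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.h_true <= 1:
            raise ValueError("h_true must be in (0, 1]")
        if self.noise_sd < 0 or self.replicates < 1:
            raise ValueError("invalid noise_sd or replicates")


@dataclass
class NanoporeSimSpec:
    """Per-read LLR calls plus allele counts at a mutant position.

    Each read at a site is modified with probability f_true; modified reads
    draw llr ~ N(+llr_mu, llr_sd), unmodified ~ N(-llr_mu, llr_sd).  Allele
    counts are Binomial(depth, h_true) for the mutant base with an
    error_rate fraction of reads reassigned to random other bases.
    """

    sites: list  # (chromosome, position, f_true)
    reads_per_site: int = 50
    llr_mu: float = 3.0
    llr_sd: float = 1.0
    mut_position: int = 13513
    h_true: float = 0.5
    depth: int = 1000
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for chrom, pos, f in self.sites:
            if not 0 <= f <= 1:
                raise ValueError(f"f_true out of range at {chrom}:{pos}")
        if self.llr_mu <= 0 or self.llr_sd <= 0:
            raise ValueError("llr_mu and llr_sd must be positive")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        if self.depth < 1 or self.reads_per_site < 1:
            raise ValueError("depth and reads_per_site must be >= 1")
        if not 0 <= self.h_true <= 1:
            raise ValueError("h_true must be in [0, 1]")


# --------------------------------------------------------------------------

def simulate_epic(spec: EpicSimSpec):
    """Generate (BetaMatrix, manifest, truth) with planted consecutive runs.

    Group means at planted probes differ from baseline by exactly delta
    (before noise) in the affected-load samples; the truth table lists one
    row per planted run with its probe ids and direction.
    """
    rng = np.random.default_rng(spec.seed)

    probe_ids, chroms, positions = [], [], []
    index_of = {}
    for chrom, n in spec.chromosomes:
        for i in range(n):
            pid = f"cg_{chrom}_{i:05d}"
            index_of[(chrom, i)] = len(probe_ids)
            probe_ids.append(pid)
            chroms.append(chrom)
            positions.append(1000 * i + 1)
    n_probes = len(probe_ids)

    samples = list(spec.groups)
    affected = np.array([spec.groups[s][1] in spec.affected_loads
                         for s in samples])

    mean = np.full((n_probes, len(samples)), spec.baseline_beta)
    truth_rows = []
    for chrom, start, length, delta in spec.planted_runs:
        rows = [index_of[(chrom, start + i)] for i in range(length)]
        for r in rows:
            mean[r, affected] = np.clip(spec.baseline_beta + delta, 0.0, 1.0)
        truth_rows.append({
            "chromosome": chrom, "start_index": start, "length": length,
            "delta": delta, "direction": "hyper" if delta > 0 else "hypo",
            "probe_ids": tuple(probe_ids[r] for r in rows)})

    if spec.noise_model == "truncnorm":
        vals = mean + rng.normal(0.0, spec.noise_sd, mean.shape)
        vals = np.clip(vals, 0.001, 0.999)
    else:
        logit = np.log(mean / (1 - mean)) + rng.normal(
            0.0, spec.noise_sd, mean.shape)
        vals = 1.0 / (1.0 + np.exp(-logit))
    if spec.noise_sd == 0:
        vals = np.clip(mean, 0.001, 0.999)

    if spec.missing_rate > 0:
        mask = rng.random(vals.shape) < spec.missing_rate
        vals = np.where(mask, np.nan, vals)

    values = pd.DataFrame(vals, index=pd.Index(probe_ids, name="probe_id"),
                          columns=samples)
    design = pd.DataFrame(
        {"mutation_type": [spec.groups[s][0] for s in samples],
         "load": [spec.groups[s][1] for s in samples]},
        index=pd.Index(samples, name="sample_id"))
    design["group"] = [_group_label(m, l) for m, l in
                       zip(design["mutation_type"], design["load"])]
    manifest = pd.DataFrame({
        "probe_id": probe_ids, "chromosome": chroms, "position": positions,
        "gene_labels": [frozenset({f"GENE{ i // 10 }_{c}"})
                        for i, c in zip(range(n_probes), chroms)],
        "strand": "unknown"})
    from .io import manifest_from_frame
    manifest["gene_labels"] = [";".join(sorted(g))
                               for g in manifest["gene_labels"]]
    manifest = manifest_from_frame(manifest)

    truth = pd.DataFrame(truth_rows)
    logger.info("simulated beta matrix %d probes x %d samples, %d planted runs",
                n_probes, len(samples), len(truth_rows))
    return BetaMatrix(values=values, design=design), manifest, truth


def _group_label(mutation_type: str, load: str) -> str:
    if load == "none":
        return mutation_type
    suffix = {"low": "L", "high": "H"}.get(load, load)
    return f"{mutation_type}{suffix}"


def simulate_ct(spec: CtSimSpec) -> pd.DataFrame:
    """Tidy CT table (sample, target, ct) with ``replicates`` rows per target."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for r in range(spec.replicates):
        noise = rng.normal(0.0, spec.noise_sd, 3) if spec.noise_sd > 0 \
            else np.zeros(3)
        rows.append(("s1", "all", spec.base_ct + noise[0]))
        rows.append(("s1", "mut",
                     spec.base_ct - np.log2(spec.h_true) + noise[1]))
        rows.append(("s1", "ref",
                     spec.base_ct + spec.ref_offset + noise[2]))
    return pd.DataFrame(rows, columns=["sample", "target", "ct"])


def simulate_nanopore(spec: NanoporeSimSpec):
    """Generate (per-read calls DataFrame, allele counts dict)."""
    rng = np.random.default_rng(spec.seed)
    recs = []
    for chrom, pos, f in spec.sites:
        modified = rng.random(spec.reads_per_site) < f
        llr = np.where(modified,
                       rng.normal(spec.llr_mu, spec.llr_sd, spec.reads_per_site),
                       rng.normal(-spec.llr_mu, spec.llr_sd, spec.reads_per_site))
        for r in range(spec.reads_per_site):
            recs.append((f"read_{chrom}_{pos}_{r}", chrom, pos, llr[r]))
    calls = pd.DataFrame(recs, columns=["read_id", "chromosome", "position",
                                        "llr"])

    n_mut = rng.binomial(spec.depth, spec.h_true)
    counts = {"A": int(n_mut), "C": 0, "G": int(spec.depth - n_mut), "T": 0}
    if spec.error_rate > 0:
        bases = list("ACGT")
        for true_base in ("A", "G"):
            n_err = rng.binomial(counts[true_base], spec.error_rate)
            counts[true_base] -= n_err
            for _ in range(n_err):
                other = [b for b in bases if b != true_base]
                counts[rng.choice(other)] += 1
    return calls, counts


def simulate_archetypes(n_probes: int = 120, n_per_group: int = 4,
                        level_gap: float = 0.3, noise_sd: float = 0.05,
                        seed: int = 0):
    """Beta matrix with three well-separated group archetypes.

    Probes are split into three blocks; within each block the three
    archetypes sit at methylation levels 0.2 / 0.2+gap / 0.2+2*gap in a
    rotating assignment, so every pair of archetypes differs by at least
    ``level_gap`` on two thirds of the probes.  Returns (BetaMatrix,
    true_labels) where true_labels gives each sample's archetype index.
    """
    rng = np.random.default_rng(seed)
    samples = [f"g{k}_s{r}" for k in range(3) for r in range(n_per_group)]
    labels = np.repeat(np.arange(3), n_per_group)
    mean = np.empty((n_probes, len(samples)))
    for p in range(n_probes):
        block = p % 3
        for s, k in enumerate(labels):
            mean[p, s] = 0.2 + level_gap * ((block + k) % 3)
    vals = np.clip(mean + rng.normal(0.0, noise_sd, mean.shape), 0.001, 0.999)
    values = pd.DataFrame(
        vals, index=[f"cg{p:05d}" for p in range(n_probes)], columns=samples)
    design = pd.DataFrame(
        {"mutation_type": [f"arch{k}" for k in labels],
         "load": "none"},
        index=pd.Index(samples, name="sample_id"))
    return BetaMatrix(values=values, design=design), labels


# --------------------------------------------------------------------------

def study_like_spec(seed: int = 0, n_probes_per_chrom: int = 87,
                    delta: float = 0.4, noise_sd: float = 0.05,
                    missing_rate: float = 0.01) -> EpicSimSpec:
    """The study-like fixture: 5 groups x 3 samples, ~2,000 probes over 23
    nuclear chromosomes plus a 7-probe chrM, planted runs 75% hypermethylated.

    High-load samples carry 40 planted runs of length 3-5 (30 hyper, 10
    hypo) scattered over the nuclear chromosomes; chrM gets none, mirroring
    the absence of differential mitochondrial methylation.
    """
    rng = np.random.default_rng(seed)
    chromosomes = [(f"chr{i}", n_probes_per_chrom) for i in range(1, 23)]
    chromosomes.append(("chrX", n_probes_per_chrom))
    chromosomes.append(("chrM", 7))

    groups = {}
    for label, (mut, load) in {
        "WT": ("WT", "none"), "13L": ("mut13", "low"),
        "13H": ("mut13", "high"), "8L": ("mut8", "low"),
        "8H": ("mut8", "high"),
    }.items():
        for r in range(1, 4):
            groups[f"{label}_{r}"] = (mut, load)

    planted = []
    occupied: dict = {}
    directions = [1] * 30 + [-1] * 10  # 75% hypermethylated
    rng.shuffle(directions)
    for sign in directions:
        while True:
            chrom = f"chr{rng.integers(1, 23)}"
            length = int(rng.integers(3, 6))
            start = int(rng.integers(0, n_probes_per_chrom - length))
            span = occupied.setdefault(chrom, set())
            # keep a 1-probe buffer so adjacent runs stay distinct
            idx = set(range(start - 1, start + length + 1))
            if not (span & idx):
                span |= idx
                break
        planted.append((chrom, start, length, sign * delta))

    return EpicSimSpec(chromosomes=chromosomes, groups=groups,
                       planted_runs=planted, baseline_beta=0.4,
                       noise_sd=noise_sd, missing_rate=missing_rate,
                       seed=seed)
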
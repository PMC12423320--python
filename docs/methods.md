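# Methods

## Beta values, deltas and significance

Array methylation is expressed as the beta value
β = max(M, 0) / (|U| + |M| + 100), where M and U are the methylated- and
unmethylated-allele fluorescence intensities (arbitrary units, negative
values possible before correction). The +100 offset keeps low-intensity
probes away from 0/0 and bounds β in [0, 1). The pipeline starts from beta
values; background correction, dye-bias equalization and BMIQ normalization
are upstream, published procedures and are out of scope here.

For a comparison of a test against a control group, each probe gets
Δ = mean(β, test) − mean(β, control) over non-missing samples, and a
one-tailed unpaired Student's *t* test (pooled variance by default; Welch
by flag) taken in the direction of the observed Δ. The one-tailed choice
follows the convention that hyper- and hypomethylation are each tested in
their own direction; a two-tailed flag exists. No multiple-testing
correction is applied by default — significance is raw *p* < α combined
with the run criterion below — and an optional Benjamini–Hochberg flag is
provided for users who want it. Probes with fewer than
`min_obs_per_group = 2` non-missing observations in either group are
marked excluded rather than silently dropped, because an excluded probe
still occupies its manifest position and must break runs.

Degenerate cases: zero variance in both groups with equal means gives
*p* = 1 (direction none); with distinct means the *t* statistic diverges
and *p* is 0.

## The consecutive-CpG run rule

A differentially methylated region (DMR) is a maximal run of at least
`min_run = 2` probes that are **adjacent in the genomic sort order of the
supplied manifest**, on one chromosome, each individually significant
(|Δ| ≥ threshold and *p* < α) in the same direction. Adjacency is defined
on the full manifest, not on the tested subset: an intervening manifest
probe that is excluded, untested or non-significant breaks the run.
Defining adjacency on the tested subset instead would let two distant
significant probes appear "consecutive" merely because everything between
them failed QC, inflating calls. Manifest order is a total order
(chromosome by natural order chr1..chr22, chrX, chrY, chrM, then position,
then probe id), so the caller's output is independent of input row order.

There is no default cap on the genomic gap between adjacent run members
(`max_gap_bp = None`); the rule as stated is purely ordinal. A configurable
cap exists for users who want bounded runs.

Threshold presets: ±0.2 (the default criterion), ±0.4 (mutant vs
wild-type) and ±0.27 (high vs low heteroplasmy).

Runs map to genes by the union of member-probe gene labels; in the
per-gene table each run supports its genes with its full probe count, a
gene backed by both directions gets the majority direction, and exact ties
are reported as "mixed". A generic hypergeometric upper-tail test stands
in for external enrichment services.

Coordinates are 1-based internally (array-manifest convention); the
bedMethyl reader converts its 0-based half-open intervals on input.
Chromosome names are normalized to "chr"-prefixed UCSC form ("MT" → "chrM").
5mC and 5hmC records for one site are kept distinct and combined on request
by summing modified counts against the shared valid coverage. Strand is
recorded but never used to merge sites.

## MS-MLPA statistics

The assay reports one mean methylation fraction per CpG site and condition.
Filters operate on those group means exactly as stated: first remove sites
at exactly 0% in every group, then remove sites with any missing group
value. Both filters are idempotent and commute with column permutation.

The group comparison is a Friedman test with sites as blocks and groups as
treatments: values are ranked within each site (average ranks for ties)
and the tie-corrected chi-square
χ² = (k−1)[ΣR_j² − n²k(k+1)²/4] / [Σr_ij² − nk(k+1)²/4]
is referred to χ²(k−1). A fully tied table (0/0) is reported as statistic
0, *p* = 1. Dunn's post hoc compares mean ranks,
z = (R̄_i − R̄_j)/√(k(k+1)/6n), with two-sided normal tails adjusted by
Bonferroni over all pairs (Holm by flag) — the classical reading of
"Dunn's Multiple Comparison Test".

## ΔCT heteroplasmy and mtDNA content

Heteroplasmy = 2^−(mutCT − allCT); mtDNA content = 2^−(allCT − refCT) with
a nuclear reference gene (B2M). The base 2 assumes perfect amplification
efficiency; an efficiency parameter generalizes 2 → (1+E) for sensitivity
analysis only. Replicate CTs for one (sample, target) are averaged on the
CT scale before the formulas. Estimates above 1 — possible at high
heteroplasmy when plate noise makes the mutant amplicon cross threshold
first — are clamped to 1 with a warning rather than rejected. Note that
because CT noise enters multiplicatively (estimate = h·2^ε), the estimator
is median-unbiased but its absolute error scales with h. The primer
sequences for the assays are shipped in `heteroshift/data/qpcr_primers.tsv`
for documentation; the package does no primer design.

## Nanopore summarization

Per-read calls carry a log-likelihood ratio (LLR); a read is counted
modified when LLR > cutoff and unmodified when LLR < −cutoff, with
`llr_cutoff = 0` (the sign) by default and reads in the ambiguous band
discarded and tallied. Site counts become a log-methyl ratio
LMR = ln((mod+c)/(unmod+c)) with pseudocount c = 1, and the logistic
sigmoid P = 1/(1+e^−LMR) maps it to (mod+c)/(mod+unmod+2c) — a smoothed
count fraction. The natural log with c = 1 is fixed here because it makes
the printed sigmoid invert the ratio exactly; an upstream tool may use a
different base or pseudocount, which changes values by a monotone
transform and therefore preserves the ordering of chromosome medians.
With c = 0 a zero count saturates P to exactly 0 or 1 and is flagged.

Per-chromosome summaries are medians of site probabilities (midpoint
convention for even counts); conditions are compared by the Wilcoxon
matched-pairs signed-rank test over chromosomes, zero differences dropped,
exact null distribution for ≤ 25 informative pairs. Both one- and
two-sided alternatives are available. Variant heteroplasmy from a pileup
is mut/(mut+wt) counts — A/(A+G) for the m.13513 G>A site — with other
bases ignored but logged.

## Clustering

Distances are Manhattan sums over pairwise-complete coordinates, rescaled
by (total/shared) coordinates; a pair sharing under 50% of coordinates is
an error rather than a guess. Linkage is UPGMA (inter-cluster distance =
mean over all cross pairs, implemented by the size-weighted Lance–Williams
update). Tie-breaking is deterministic: among minimum-distance pairs the
one whose smallest original leaf index is lowest merges first, so
dendrograms are reproducible across platforms; on tie-free input the tree
agrees with any standard UPGMA (verified against an independent all-pairs
oracle and scipy). Cutting removes the k−1 highest merges and numbers
groups stably by leftmost leaf. Newick export writes branch lengths so
that each leaf's root distance equals the final merge height (ultrametric
reading).

## Synthetic data: what it does and does not emulate

The generators realize exactly the assumptions the analyses make, no more:

- **Beta matrices**: a constant baseline with planted runs of consecutive
  probes shifted by exactly Δ in the affected (high-load) samples, i.i.d.
  truncated-normal noise on the beta scale clipped to [0.001, 0.999]
  (logit-normal by flag), and uniform missingness. Real arrays have
  probe-specific baselines, spatially correlated noise, batch effects and
  type-I/II probe chemistry differences; passing the recovery tests shows
  the caller's logic is correct under its stated model, not that array
  artifacts are handled.
- **The study-like preset**: 5 groups (WT, 13L, 13H, 8L, 8H) × 3 samples,
  2,000 nuclear probes over 23 chromosomes plus a 7-probe chrM carrying no
  planted signal, 40 planted runs of length 3–5 at Δ = 0.4 of which 75%
  are hypermethylated — mirroring the design in which hypermethylation
  dominates among differential sites and mtDNA probes show no differential
  methylation. Both high-load groups share the planted archetype, so
  "high vs low" pools six samples a side.
- **CT triples**: allCT = base + ε, mutCT = base − log₂(h) + ε′ with
  independent Gaussian ε (sd 0.1 in the recovery checks — a typical
  technical-replicate spread), so the noiseless case inverts exactly.
  Efficiency differences between amplicons are not simulated.
- **Nanopore reads**: modified with probability f, LLR from
  N(±llr_mu, llr_sd) — a two-component caricature of basecaller output
  with no read-length, mappability or strand structure. Allele counts are
  Binomial(depth, h) with an optional ≤ 5% error reassignment.
- A separate three-archetype generator provides well-separated clusters
  (level gap 0.3, noise sd 0.05) for clustering-recovery checks.

All generators take explicit seeds and use no global random state; the
same seed reproduces byte-identical outputs.

## Problem sizes and numerical choices

The recovery checks run at deliberately modest sizes chosen to exercise
the statistics, not the I/O: 200 simulations for planted-run recovery
(30 probes, n = 6/group), 500 replicates × 9 heteroplasmy levels for ΔCT
recovery, 200 random instances for the run-caller oracle, 100 seeded runs
for clustering recovery, 8-leaf matrices for the UPGMA oracle (where the
brute-force oracle is quadratic per merge). The end-to-end fixture uses
~2,000 probes rather than 850k; the caller is vectorized per probe and
scales linearly, and nothing in the run rule depends on matrix size.

Tolerances: algebraic identities (sigmoid/count fraction, BR = ATP + PL,
ΔCT consistency) are asserted to ~1e-12 relative; oracle equivalences to
1e-9; Monte-Carlo recoveries at the bounds stated above. Excluded probes
propagate as NaN, never zero. The MS-MLPA zero filter compares against
exactly 0.0, as the rule is stated on reported percentages.

## Known limitations

- The DMR caller tests each probe marginally; it models no spatial
  correlation and borrows no strength across probes (no smoothing à la
  bump hunting). That is faithful to the criterion it implements.
- With default settings p-values are raw; the run criterion is the only
  guard against multiplicity, as in the original criterion.
- The Friedman/Dunn machinery assumes one value per (site, group); it does
  not model replicate-level variance within groups.
- bedMethyl parsing accepts the ModKit 18-column dialect and a minimal
  6-column form; other dialects need the per-read TSV path.
- `plot_heatmap` is a minimal diagnostic and is intentionally untested.
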
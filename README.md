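# aneuscreen

Analysis toolkit for a classic experiment in yeast stress genetics: a
mutagenesis-free screen in which haploid *Saccharomyces cerevisiae*
segregants are selected for increased hydrogen peroxide tolerance, the
surviving mutants are whole-genome sequenced, and the most frequent causal
lesion turns out to be an extra copy of all (or the right arm) of
chromosome IV. `aneuscreen` re-implements the computational machinery such
a screen needs, end to end, and ships a synthetic-data module so every
stage is testable against a known truth set without any sequencing
downloads.

It is aimed at people analyzing haploid yeast (or other small-genome
haploid) resequencing screens: mutation calling against progenitor-specific
references, coverage-based aneuploidy detection, chromosome-truncation
mapping, and the screen's phenotype arithmetic.

## What it computes

**Variant calling and reference refinement** (`aneuscreen.variants`).
A site in a pileup is called a mutation when a single non-reference allele
is supported by at least 90% of the reads (boundary inclusive), with a
configurable depth floor (default 10 reads). Progenitor-specific reference
genomes are built iteratively: call differences between the progenitor's
pileup and the current reference, integrate them (SNVs in place, indels
shifting downstream coordinates), regenerate the pileup, and repeat for up
to 10 cycles or until a cycle finds nothing new. Mutant mutations are then
called against the refined progenitor reference, classified as
nonsynonymous / synonymous / intergenic by codon translation, and
deduplicated across mutants on (chrom, pos, ref, alt).

**Coverage-based ploidy calling** (`aneuscreen.ploidy`). Per-site depths
are averaged in 1 kb windows and scaled to the genome-wide per-site mean.
Each chromosome's windows are rounded against a euploid baseline (median
of per-chromosome medians); a chromosome is *whole*-duplicated when ≥95%
of windows share a modal copy number > 1, otherwise a single-changepoint
scan (least-squares two-level fit) looks for a terminal *segmental*
duplication. A cohort summary reports the fraction of mutants disomic for
a focal chromosome arm.

**PCD design and interval mapping** (`aneuscreen.pcd_mapping`).
PCR-mediated chromosomal deletion constructs truncate a chromosome at an
insertion site: a 300–600 bp homology arm, a selection cassette, and a
synthetic telomere seed (six repeats of 5′-CCCCAA-3′), joined by overlap
fusion PCR with 30-base primer tails. Truncating at position *p* deletes
[*p*, telomere], so a reverted phenotype proves the causal element lies at
or beyond *p*; a monotone panel of staggered truncations brackets the
causal element, and `infer_interval` returns that bracket (half-open,
`[max reverting, min retaining)`).

**Screen phenotypes and qPCR** (`aneuscreen.phenotype`). MIC = lowest dose
with no growth; the screen keeps mutants whose MIC exceeds their
progenitor's by ≥1.0 mM initially and ≥0.5 mM at confirmation; relative
locus copy number comes from the ΔΔCq model against a single-copy
reference gene; replicate summaries use 95% t-intervals over biological
replicates with technical replicates pre-averaged.

**Synthetic data** (`aneuscreen.synthetic_data`). Generates multi-
chromosome haploid genomes, progenitors differing from the base reference
by SNVs/small indels, mutants carrying point mutations / whole-chromosome
disomies / terminal segmental duplications, per-site pileups obeying
`depth = mean_depth × copy_number` (exact when noiseless, Poisson
otherwise), plus screen MIC and qPCR Cq fixtures — all with complete truth
records.

## Worked example

```
aneuscreen run-all --out demo_out --seed 42
```

runs the full synthetic screen: cohort generation, reference refinement,
mutation calling and classification, ploidy calling, and truth scoring.
It prints:

```
{
 "recovery": {
  "n_called_snv_instances": 44,
  "n_planted_disomies": 2,
  "n_planted_snv_instances": 44,
  "snv_precision": 1.0,
  "snv_sensitivity": 1.0
 },
 "unique_by_effect": {
  "intergenic": 9,
  "nonsynonymous": 22,
  "synonymous": 8
 },
 "unique_mutations": 39
}
```

Reading: the ten simulated mutants carry 44 point-mutation instances (39
distinct mutations, five of which recur in a second mutant); on noiseless
100× pileups every instance is recovered with no false positives
(sensitivity and precision 1.0), and cross-mutant deduplication returns
the 39 unique mutations split 22 nonsynonymous / 8 synonymous / 9
intergenic. Full tables (per-mutant calls, ploidy calls, cohort summary,
refinement log) land in `demo_out/`.

Other entry points: `aneuscreen simulate | refine | call | ploidy |
pcd-design | pcd-map | phenotype | qpcr` (see `--help` on each), or use
the library modules directly.

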
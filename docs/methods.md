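# Methods

This note documents the models, defaults and numerical choices behind
`aneuscreen`, and what the synthetic study conditions do and do not show
about real sequencing data.

## Coordinate and data conventions

All in-memory coordinates are 1-based inclusive (the SAM/mpileup
convention); BED output alone is converted to 0-based half-open at the
file boundary. Causal intervals from truncation mapping are half-open
`[lower, upper)`: the retaining truncation's own position is excluded
because its deletion did not remove the causal element.

The native pileup dialect is a dense per-site TSV
(`chrom pos ref depth A C G T ins del`); indel evidence is anchored at the
site preceding the event, mpileup-style, as `SEQ:COUNT` tokens. An adapter
parses 6-column `samtools mpileup` text (handling `^`/`$`, `*` and
`+N`/`-N` tokens) so externally aligned data can enter the pipeline; only
the majority indel sequence per site is retained, matching the caller's
single-alternate-allele model.

## Variant calling

A site is called iff `depth ≥ min_depth` **and** a single non-reference
allele reaches `min_fraction` of the depth, boundary inclusive. Defaults:

- `min_fraction = 0.90` — the haploid-screen rule; at 100× a true
  homozygous mutation sits near fraction 1.0 and a variant present on one
  of two copies of a disomic chromosome sits near 0.50, so the threshold
  cleanly separates clonal point mutations from copy-specific ones.
- `min_depth = 10` — a depth floor preventing one- or two-read "100%"
  calls. This is a package choice, configurable, not part of the 90% rule.
- `max_indel_bp = 50` — only small indels are modeled; the anchored
  single-token pileup representation does not suit larger events.

Multi-allelic sites: each alternate allele is evaluated independently; at
a threshold above 0.5 at most one allele can qualify, so a tie between two
sub-threshold alternates is no call.

## Reference refinement

Progenitor-specific references are built by iterating call → integrate
until a cycle yields zero variants (converged) or 10 cycles have run.
Integration applies SNVs in place and indels right-to-left per chromosome,
so pending coordinates stay valid and the result is independent of input
order; overlapping variants are rejected with the collision listed. A
composed coordinate map (old base position → refined position, `None` for
deleted bases) is returned so positions planned against the base reference
can be carried into the refined frame.

Convergence is defined as *zero new variants in a cycle*; on noiseless
synthetic progenitors refinement reaches the exact progenitor haplotype in
two cycles and is a fixed point (re-refining its own output finds
nothing).

## Effect classification

SNVs inside an annotated feature are classified by translating the
affected codon on the feature's strand with the standard genetic code;
identical amino acids ⇒ synonymous. Dubious ORFs are still ORFs and are
classified like genes. Positions outside every feature are intergenic.
Indels carry `not_applicable`. Annotated features are required to have
codon-multiple lengths and may not overlap (the generator places all
features disjointly, so classification is unambiguous).

## Coverage-based ploidy

Per-site depths are averaged in fixed windows (default 1,000 bp; the final
partial window keeps its true length — on the 1/10-scale toy genome the
smallest chromosome still has ≥ 20 windows). Window means are scaled to
the genome-wide per-site mean; the length-weighted mean of scaled values
is exactly 1 by construction.

Classification baseline: the **median of per-chromosome median scaled
values**, not the genome mean — a duplicated chromosome large enough to
matter also inflates the mean it would otherwise be judged against
(chromosome IV is ~13% of the yeast genome). This estimator assumes the
majority of chromosomes are euploid; with ≤ 3 of 16 chromosomes disomic
the baseline stays within 1% of the true single-copy level. Display
plotting keeps the plain genome-mean scaling.

Per-window copy number is `round(scaled / baseline)` clipped to
`[1, cn_max=4]`. A chromosome is *whole*-duplicated when ≥ 95%
(`whole_chrom_fraction`) of windows share a modal copy number > 1.
Otherwise a single-changepoint scan fits a two-level piecewise-constant
model by least squares over all split points leaving ≥ 10 windows
(`min_segment_windows`) per side — computed by prefix sums, equivalent to
the exhaustive scan, leftmost split on ties — and returns a segmental call
only when the two segment means round to different copy numbers. The
breakpoint is reported at the left edge of the right segment, so a
noiseless step at a window boundary is recovered exactly and any step is
localized within one window. Scaled levels within ±0.15 of a half-integer
multiple of the baseline are flagged low-confidence. One changepoint per
chromosome only: terminal arm duplications are the modeled event class;
interstitial or multi-segment patterns are out of scope, as are mosaic
(sub-integer) copy numbers and GC/mappability correction.

Cohort summaries count a mutant as *arm-disomic* when its focal-chromosome
call covers the entire focal arm at copy number ≥ 2 (a whole-chromosome
disomy, or a segmental duplication spanning the arm); group percentages
are rounded to the nearest integer and an `ALL` row aggregates the screen.

## Truncation (PCD) design and mapping

Constructs are `arm + cassette + telomere_seed` with the homology arm
taken from the + strand ending at the insertion position (450 bp default,
the midpoint of the 300–600 bp working range) and a telomere seed of six
CCCCAA repeats. Overlap-fusion primers carry their 30-base fusion tails at
the 5′ end with a 20-base annealing core at the 3′ end; removing the tails
from the assembled product reconstructs each source segment exactly. The
packaged cassette sequence is a synthetic stand-in (random 1.5 kb,
labelled as such in the FASTA header); any cassette can be substituted.
Primer thermodynamics are out of scope.

Tiling places insertion positions so both region ends are included and the
gaps are as even as possible with the count closest to the ~50 kb target
spacing; a region shorter than the spacing degrades to its two endpoints.

Interval inference requires a monotone reversion pattern (every truncation
at or proximal to the most distal reverting position reverts). Violations
raise an error naming the conflicting strains — a non-monotone pattern
signals epistasis or strain mislabeling, not a smaller interval. With no
retaining truncation beyond the reverting ones the upper bound is censored
at the region end and flagged.

## Phenotype arithmetic

"Grew on doses at least X mM higher than the progenitor" is
operationalized as a MIC difference ≥ X (inclusive): stage deltas 1.0 mM
(initial) and 0.5 mM (confirmation). Censored candidates (growth at every
tested dose) are always kept, flagged as lower bounds; a censored
progenitor is an error since no gain can be computed. Non-monotone growth
patterns return the literal lowest no-growth dose with a warning.

qPCR copy number uses ΔΔCq with a fixed amplification efficiency of 2.0
(configurable): `quantity = E^-(ΔCq_sample − ΔCq_calibrator)` with
ΔCq = mean target Cq − mean reference Cq per sample. The estimator is
unbiased in log space; with 4 replicates at σ = 0.1 cycles a 2-copy locus
is recovered within ±5%.

Replicate summaries average technical replicates within each biological
replicate first and compute `mean ± t(0.975, n−1)·sd/√n` over the n
biological means; n = 1 returns the mean with the CI flagged undefined.
Endpoint growth measurements are treated as plain numbers; no
dose–response curve fitting.

## Synthetic study conditions

The generator's defaults define the conditions the tests run under:

- Default toy genome: a 1/10-scale miniature of the 16 yeast nuclear
  chromosomes (~1.2 Mb; chromosome IV → 153,400 bp with the right-arm
  boundary at 64,401), so whole-genome runs finish in seconds while
  preserving the relative-size geometry that the baseline estimator and
  arm-fraction arithmetic depend on. Full-scale single chromosomes
  (1,534,000 bp with the duplication boundary at 644,001) are used where
  the printed geometry itself is under test. Mitochondrial and 2-micron
  sequences are not modeled.
- Sequencing model: per-site expected depth `mean_depth × copy_number`
  (default 100×), exact under `noise="none"`, Poisson otherwise; errors
  replace the true base uniformly with one of the other three at
  `error_rate` (default 0). No quality scores — the calling rule uses read
  fractions only. Reads are never simulated individually; the pileup is
  produced directly by globally aligning the sample haplotype to the
  current reference (edlib) and translating the alignment into per-site
  observations. In locally ambiguous contexts the aligner may represent a
  planted indel by an equivalent shifted or split alignment; calling and
  integrating those observations still reconstructs the sample haplotype
  exactly, which is the property the pipeline relies on.
- Packaged cohort (fixture seed 42): one progenitor (6 SNVs + 2 small
  indels from the base reference, exercising refinement across coordinate
  shifts), ten mutants sharing 39 unique planted point mutations
  (22 nonsynonymous / 8 synonymous / 9 intergenic — the screen's reported
  composition), five of them recurring in a second mutant to exercise
  deduplication, plus two chromosome disomies.
- Packaged screen fixture (seed 42): three crosses with progenitor MICs
  7.0/8.5/8.5 mM on a 0.5 mM dose grid; per-cross confirmation-pass counts
  14/9/14 with gain pools whose means land near the reported 2.3/2.1/0.6
  mM; fail counts 6/5/4 are package choices.

What passing these tests does **not** show about real data: the simulator
has no mapping artifacts, repeat-induced coverage structure, GC bias,
contamination, or base-quality variation, so the exact-recovery results
(100% sensitivity/precision, exact copy numbers) are statements about the
pipeline's logic, not about expected performance on real libraries. The
90% rule's robustness is probed only with uniform error rates up to 5%.

## Determinism

Every operation is a pure function of its inputs and seed. Pipeline
outputs round floats before serialization and sort JSON keys; re-running
with the same config and seed reproduces reports byte for byte.
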
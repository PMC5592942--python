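"""Synthetic genomes, mutant cohorts, pileups and phenotype fixtures.

Everything downstream of read alignment is exercised on data generated
here with a known truth set: a multi-chromosome haploid genome, progenitor
strains that differ from the base reference by SNVs and small indels, and
mutant strains carrying point mutations, whole-chromosome disomies, or a
terminal segmental duplication. Pileups are simulated directly at the
per-site level (reads themselves are never modeled): the expected depth of
a site is ``mean_depth x copy_number``, optionally Poisson-distributed,
and sequencing errors replace the true base with one of the three other
bases uniformly at ``error_rate``.

The pileup simulator aligns the sample haplotype to an arbitrary reference
genome (edlib, global alignment), so the same code path serves both the
progenitor-vs-base refinement loop and mutant-vs-refined-progenitor
calling.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd

from .core import BASES, GeneAnnotation, Genome, Interval, ValidationError, translate_codon
from .pileup import ChromPileup, Pileup
from .variants import integrate_variants

# the three alternatives to each true base, A/C/G/T order
_ALT_LUT = np.array([[j for j in range(4) if j != i] for i in range(4)])


# -- genome simulation ---------------------------------------------------


@dataclass(frozen=True)
class GenomeSpec:
    """Shape of a simulated haploid genome."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    gc_fraction: float = 0.38
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValidationError("chrom_names and chrom_lengths lengths differ")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValidationError("chrom_names must be unique")
        if any(n < 1 for n in self.chrom_lengths):
            raise ValidationError("chrom_lengths must all be >= 1")
        if not 0 <= self.gc_fraction <= 1:
            raise ValidationError("gc_fraction must be in [0, 1]")


#: 1/10-scale miniature of the 16 S. cerevisiae nuclear chromosomes
#: (~1.2 Mb total) so whole-genome runs finish in seconds. chrIV keeps the
#: geometry that matters for arm-duplication tests: length 153,400 with the
#: right-arm duplication breakpoint at 64,401.
SCALED_YEAST_LENGTHS: dict[str, int] = {
    "chrI": 23000, "chrII": 81300, "chrIII": 31700, "chrIV": 153400,
    "chrV": 57700, "chrVI": 27000, "chrVII": 109100, "chrVIII": 56300,
    "chrIX": 44000, "chrX": 74600, "chrXI": 66700, "chrXII": 107800,
    "chrXIII": 92400, "chrXIV": 78400, "chrXV": 109100, "chrXVI": 94800,
}


def default_genome_spec(seed: int = 0) -> GenomeSpec:
    return GenomeSpec(
        chrom_names=tuple(SCALED_YEAST_LENGTHS),
        chrom_lengths=tuple(SCALED_YEAST_LENGTHS.values()),
        gc_fraction=0.38,
        seed=seed,
    )


def simulate_genome(spec: GenomeSpec) -> Genome:
    """Draw i.i.d. bases with GC content ``gc_fraction`` in expectation."""
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    base_arr = np.frombuffer("ACGT".encode(), dtype="S1")
    seqs = {}
    for name, length in zip(spec.chrom_names, spec.chrom_lengths):
        idx = rng.choice(4, size=length, p=p)
        seqs[name] = base_arr[idx].tobytes().decode()
    return Genome(seqs)


# -- mutation planning and planting --------------------------------------


@dataclass(frozen=True)
class PlannedSNV:
    chrom: str
    pos: int
    ref: str
    alt: str
    effect_class: str | None = None


@dataclass(frozen=True)
class PlannedIndel:
    """Anchored indel: ``seq`` is inserted immediately after ``pos``
    (insertion) or the genome bases at ``pos+1..pos+len(seq)`` are removed
    (deletion)."""

    chrom: str
    pos: int
    seq: str
    kind: str  # "insertion" | "deletion"


@dataclass
class MutationPlan:
    snvs: list[PlannedSNV] = field(default_factory=list)
    indels: list[PlannedIndel] = field(default_factory=list)
    disomies: list[str] = field(default_factory=list)
    segmental_dups: list[tuple[str, int, int]] = field(default_factory=list)

    def n_events(self) -> int:
        return (
            len(self.snvs) + len(self.indels) + len(self.disomies)
            + len(self.segmental_dups)
        )


@dataclass
class TruthRecord:
    """One planted event, for scoring recovery downstream."""

    event_type: str  # snv | insertion | deletion | disomy | segmental_dup
    chrom: str
    start: int
    end: int
    alt: str
    copy_number: int
    effect_class: str | None = None

    def fraction_of_chrom(self, chrom_length: int) -> float:
        return (self.end - self.start + 1) / chrom_length

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class MutantModel:
    """A mutant haplotype plus its copy-number map and planted truth.

    ``copy_number`` maps ``(chrom, start, end)`` (1-based inclusive, mutant
    coordinates) to an integer copy number; everything unlisted is 1.
    Point-event truth is recorded in progenitor coordinates (the frame in
    which the events will be called); copy-number truth in mutant
    coordinates.
    """

    genome: Genome
    copy_number: dict[tuple[str, int, int], int] = field(default_factory=dict)
    truth: list[TruthRecord] = field(default_factory=list)

    def cn_array(self, chrom: str) -> np.ndarray:
        n = len(self.genome.sequences[chrom])
        cn = np.ones(n, dtype=np.int64)
        for (c, start, end), value in self.copy_number.items():
            if c == chrom:
                cn[start - 1 : end] = value
        return cn

    @classmethod
    def euploid(cls, genome: Genome) -> "MutantModel":
        return cls(genome=genome)


def plant_events(progenitor: Genome, plan: MutationPlan) -> MutantModel:
    """Apply a mutation plan to a progenitor haplotype.

    Point events are substituted into the sequence (SNVs in place, indels
    shifting downstream coordinates); disomies and segmental duplications
    only raise the copy-number map — the duplicated copy is identical, so
    planted SNVs on a duplicated chromosome sit on both copies.
    """
    seen: set[tuple[str, int]] = set()
    rows = []
    for snv in plan.snvs:
        if (snv.chrom, snv.pos) in seen:
            raise ValidationError(f"two SNVs planted at {snv.chrom}:{snv.pos}")
        seen.add((snv.chrom, snv.pos))
        actual = progenitor.base_at(snv.chrom, snv.pos)
        if actual != snv.ref:
            raise ValidationError(
                f"SNV at {snv.chrom}:{snv.pos} expects ref {snv.ref} "
                f"but genome has {actual}"
            )
        if snv.alt == snv.ref or snv.alt not in BASES:
            raise ValidationError(f"bad alt allele {snv.alt!r} at {snv.chrom}:{snv.pos}")
        rows.append(
            {"chrom": snv.chrom, "pos": snv.pos, "ref": snv.ref,
             "alt": snv.alt, "type": "snv", "fraction": 1.0, "depth": 0}
        )
    for ind in plan.indels:
        anchor = progenitor.base_at(ind.chrom, ind.pos)
        if ind.kind == "insertion":
            rows.append(
                {"chrom": ind.chrom, "pos": ind.pos, "ref": anchor,
                 "alt": anchor + ind.seq, "type": "insertion",
                 "fraction": 1.0, "depth": 0}
            )
        elif ind.kind == "deletion":
            expected = progenitor.fetch(ind.chrom, ind.pos + 1, ind.pos + len(ind.seq))
            if expected != ind.seq:
                raise ValidationError(
                    f"deletion after {ind.chrom}:{ind.pos} expects {ind.seq} "
                    f"but genome has {expected}"
                )
            rows.append(
                {"chrom": ind.chrom, "pos": ind.pos, "ref": anchor + ind.seq,
                 "alt": anchor, "type": "deletion", "fraction": 1.0, "depth": 0}
            )
        else:
            raise ValidationError(f"unknown indel kind {ind.kind!r}")
    variant_df = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "type", "fraction", "depth"]
    )
    mutant_genome, cmap = integrate_variants(progenitor, variant_df)

    copy_number: dict[tuple[str, int, int], int] = {}
    truth: list[TruthRecord] = []
    for snv in plan.snvs:
        truth.append(TruthRecord("snv", snv.chrom, snv.pos, snv.pos,
                                 snv.alt, 1, snv.effect_class))
    for ind in plan.indels:
        end = ind.pos if ind.kind == "insertion" else ind.pos + len(ind.seq)
        truth.append(TruthRecord(ind.kind, ind.chrom, ind.pos, end, ind.seq, 1))
    duplicated_chroms: set[str] = set()
    for chrom in plan.disomies:
        if chrom not in mutant_genome.sequences:
            raise ValidationError(f"disomy chromosome {chrom!r} not in genome")
        if chrom in duplicated_chroms:
            raise ValidationError(f"overlapping duplication events on {chrom}")
        duplicated_chroms.add(chrom)
        n = len(mutant_genome.sequences[chrom])
        copy_number[(chrom, 1, n)] = 2
        truth.append(TruthRecord("disomy", chrom, 1, n, "", 2))
    for chrom, start, end in plan.segmental_dups:
        if chrom in duplicated_chroms:
            raise ValidationError(f"overlapping duplication events on {chrom}")
        duplicated_chroms.add(chrom)
        if start > end:
            raise ValidationError(f"segmental duplication start > end on {chrom}")
        new_start = cmap.map(chrom, start)
        new_end = cmap.map(chrom, end)
        if new_start is None or new_end is None:
            raise ValidationError(
                f"segmental duplication endpoint on {chrom} falls in a deletion"
            )
        n = len(mutant_genome.sequences[chrom])
        if not 1 <= new_start <= new_end <= n:
            raise ValidationError(f"segmental duplication outside {chrom}")
        if new_start == 1 and new_end == n:
            raise ValidationError(
                f"segmental duplication spans all of {chrom}; plant a disomy instead"
            )
        copy_number[(chrom, new_start, new_end)] = 2
        truth.append(TruthRecord("segmental_dup", chrom, new_start, new_end, "", 2))
    return MutantModel(genome=mutant_genome, copy_number=copy_number, truth=truth)


# -- annotation ----------------------------------------------------------


def generate_annotation(genome: Genome, n_genes: int, seed: int = 0) -> GeneAnnotation:
    """Place ``n_genes`` non-overlapping coding features at random.

    Feature lengths are random multiples of 3 between 300 and 897 bp;
    roughly one in eight features is labelled a dubious ORF. Features never
    overlap, regardless of strand, so effect classification is unambiguous.
    """
    rng = np.random.default_rng(seed)
    lengths = genome.lengths
    chrom_names = list(lengths)
    weights = np.array([lengths[c] for c in chrom_names], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    rows = []
    attempts_left = 400 * n_genes
    n_placed = 0
    while n_placed < n_genes:
        if attempts_left <= 0:
            raise ValidationError(
                f"could not place {n_genes} non-overlapping genes on this genome"
            )
        attempts_left -= 1
        chrom = chrom_names[rng.choice(len(chrom_names), p=weights)]
        length = 3 * int(rng.integers(100, 300))
        if lengths[chrom] <= length + 2:
            continue
        start = int(rng.integers(1, lengths[chrom] - length + 1))
        end = start + length - 1
        if any(s <= end and start <= e for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        n_placed += 1
        is_dubious = rng.random() < 0.125
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append(
            {
                "feature_id": (f"dORF{n_placed:04d}" if is_dubious else f"g{n_placed:04d}"),
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "feature_type": "dubious_ORF" if is_dubious else "gene",
            }
        )
    df = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    return GeneAnnotation(df)


# -- pileup simulation ---------------------------------------------------

_CIGAR_SPLIT = __import__("re").compile(r"(\d+)([=XIDM])")


def _align_sample_to_ref(sample: str, ref: str):
    """Global-align a sample chromosome to a reference chromosome.

    Returns (aligned_sample_pos, insertions, deletions) where
    ``aligned_sample_pos[i]`` is the 0-based sample index matched to
    0-based reference index ``i`` (-1 where the reference base is deleted
    in the sample); insertions are ``(ref_anchor_1based, inserted_seq)``;
    deletions are ``(ref_anchor_1based, deleted_seq)``.
    """
    n = len(ref)
    if sample == ref:
        return np.arange(n, dtype=np.int64), [], []
    res = edlib.align(sample, ref, task="path", mode="NW")
    aligned = np.full(n, -1, dtype=np.int64)
    insertions: list[tuple[int, str]] = []
    deletions: list[tuple[int, str]] = []
    qi = ti = 0
    for num, op in _CIGAR_SPLIT.findall(res["cigar"]):
        ln = int(num)
        if op in "=XM":
            aligned[ti : ti + ln] = np.arange(qi, qi + ln)
            ti += ln
            qi += ln
        elif op == "I":  # bases present in sample, absent from reference
            if ti == 0:
                raise ValidationError("insertion before reference position 1 unsupported")
            insertions.append((ti, sample[qi : qi + ln]))
            qi += ln
        elif op == "D":  # reference bases absent from sample
            if ti == 0:
                raise ValidationError("deletion at reference position 1 unsupported")
            deletions.append((ti, ref[ti : ti + ln]))
            ti += ln
    return aligned, insertions, deletions


def simulate_pileup(
    mutant: MutantModel,
    reference: Genome,
    mean_depth: int = 100,
    error_rate: float = 0.0,
    noise: str = "none",
    seed: int = 0,
) -> Pileup:
    """Simulate a per-site pileup of a mutant against any reference genome.

    Expected depth at each reference site is ``mean_depth`` times the copy
    number of the aligned sample position; ``noise="none"`` gives exact
    depths, ``noise="poisson"`` draws per-site Poisson depths. Errors
    replace the true base uniformly with one of the other three at
    ``error_rate``. Reference sites deleted in the sample keep their
    spanning-read depth but no base support; indel evidence is anchored at
    the site before the event, mpileup-style.
    """
    if mean_depth <= 0:
        raise ValidationError("mean_depth must be > 0")
    if noise not in ("none", "poisson"):
        raise ValidationError(f"unknown noise model {noise!r}")
    if not 0 <= error_rate < 1:
        raise ValidationError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    chroms: dict[str, ChromPileup] = {}
    for chrom, ref_seq in reference.sequences.items():
        if chrom not in mutant.genome.sequences:
            raise ValidationError(f"mutant genome lacks chromosome {chrom!r}")
        sample_seq = mutant.genome.sequences[chrom]
        aligned, insertions, deletions = _align_sample_to_ref(sample_seq, ref_seq)
        n = len(ref_seq)
        # forward-fill deleted sites with the sample position of the last
        # aligned base, so spanning depth uses the local copy number
        filled = np.maximum.accumulate(np.where(aligned >= 0, aligned, -1))
        filled = np.maximum(filled, 0)
        cn = mutant.cn_array(chrom)[filled]
        expected = mean_depth * cn
        if noise == "poisson":
            depth = rng.poisson(expected).astype(np.int64)
        else:
            depth = expected.astype(np.int64)
        counts = np.zeros((4, n), dtype=np.int64)
        valid = np.flatnonzero(aligned >= 0)
        sample_arr = np.frombuffer(sample_seq.encode(), dtype="S1")
        from .pileup import base_indices  # local import avoids cycle at module load

        true_idx = base_indices(sample_arr[aligned[valid]])
        d_valid = depth[valid]
        if error_rate > 0:
            n_err = rng.binomial(d_valid, error_rate)
            e1 = rng.binomial(n_err, 1 / 3)
            e2 = rng.binomial(n_err - e1, 1 / 2)
            e3 = n_err - e1 - e2
            counts[true_idx, valid] = d_valid - n_err
            counts[_ALT_LUT[true_idx, 0], valid] += e1
            counts[_ALT_LUT[true_idx, 1], valid] += e2
            counts[_ALT_LUT[true_idx, 2], valid] += e3
        else:
            counts[true_idx, valid] = d_valid
        cp = ChromPileup(
            ref=np.frombuffer(ref_seq.encode(), dtype="S1").copy(),
            depth=depth,
            counts=counts,
        )
        for anchor, seq in insertions:
            d = int(depth[anchor - 1])
            if d > 0:
                cp.ins[anchor] = (seq, d)
        for anchor, seq in deletions:
            d = int(depth[anchor - 1])
            if d > 0:
                cp.dels[anchor] = (seq, d)
        chroms[chrom] = cp
    return Pileup(chroms)


# -- phenotype / qPCR fixtures -------------------------------------------

#: per-cross confirmation-stage structure of the packaged screen fixture:
#: (progenitor MIC in mM, number of passing isolates, number failing,
#:  MIC gains the passers are drawn from — means near 2.3/2.1/0.6 mM)
SCREEN_CROSS_DESIGN: dict[str, tuple[float, int, int, tuple[float, ...]]] = {
    "BYxRM": (7.0, 14, 6, (1.5, 2.0, 2.5, 3.0)),
    "RMxYPS": (8.5, 9, 5, (1.5, 2.0, 2.5, 3.0)),
    "BYxYPS": (8.5, 14, 4, (0.5, 0.5, 1.0)),
}

DOSE_STEP_MM = 0.5


def make_screen_fixture(seed: int = 42) -> tuple[pd.DataFrame, dict]:
    """Growth tables for a three-cross tolerance screen with known truth.

    Returns a long-format table ``strain cross dose_mM grew`` covering each
    progenitor and its candidate isolates on a 0.5 mM dose grid, plus a
    truth dict mapping strain -> planted confirmation-pass flag. The
    per-cross pass counts are 14, 9 and 14 (37 total).
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth: dict[str, dict] = {"strains": {}, "pass_counts": {}}
    for cross, (prog_mic, n_pass, n_fail, gains) in SCREEN_CROSS_DESIGN.items():
        max_dose = prog_mic + 4.0
        doses = np.round(np.arange(0.0, max_dose + DOSE_STEP_MM, DOSE_STEP_MM), 2)

        def emit(strain: str, mic: float) -> None:
            for dose in doses:
                rows.append(
                    {"strain": strain, "cross": cross, "dose_mM": float(dose),
                     "grew": int(dose < mic)}
                )

        emit(f"{cross}_prog", prog_mic)
        truth["strains"][f"{cross}_prog"] = {"role": "progenitor", "mic_mM": prog_mic}
        n_total = n_pass + n_fail
        for i in range(1, n_total + 1):
            strain = f"{cross}_m{i:02d}"
            if i <= n_pass:
                gain = float(gains[rng.integers(0, len(gains))])
            else:
                gain = float(rng.choice([-0.5, 0.0, 0.0]))
            mic = prog_mic + gain
            emit(strain, mic)
            truth["strains"][strain] = {
                "role": "candidate", "mic_mM": mic, "gain_mM": gain,
                "passes_confirmation": gain >= 0.5,
            }
        truth["pass_counts"][cross] = n_pass
    return pd.DataFrame(rows), truth


def make_qpcr_fixture(seed: int = 42, n_replicates: int = 4, sigma: float = 0.1) -> pd.DataFrame:
    """Cq replicate table for a 2-copy vs 1-copy locus, relative to a
    single-copy reference gene.

    The disomic sample carries two copies of the target, so its target Cq
    sits one cycle below the euploid calibrator's at perfect efficiency.
    Gaussian noise (sd ``sigma`` cycles) is added to every replicate.
    """
    rng = np.random.default_rng(seed)
    design = {
        ("euploid_progenitor", "ACT1"): 18.0,
        ("euploid_progenitor", "TSA2"): 20.0,
        ("disomic_mutant", "ACT1"): 18.0,
        ("disomic_mutant", "TSA2"): 19.0,
    }
    rows = [
        {"sample": sample, "target": target,
         "cq": float(true_cq + rng.normal(0.0, sigma))}
        for (sample, target), true_cq in design.items()
        for _ in range(n_replicates)
    ]
    return pd.DataFrame(rows)


# -- packaged point-mutation cohort --------------------------------------

#: effect-class composition of the packaged point-mutation cohort:
#: 22 nonsynonymous + 8 synonymous + 9 intergenic = 39 unique mutations
COHORT_EFFECT_COUNTS = {"nonsynonymous": 22, "synonymous": 8, "intergenic": 9}
COHORT_N_MUTANTS = 10
COHORT_N_SHARED = 5  # mutations recurrently observed in a second mutant


@dataclass
class CohortFixture:
    """A simulated screen cohort with full truth.

    ``progenitor_model`` expresses the progenitor relative to
    ``base_reference`` (for reference refinement); each mutant model is
    expressed relative to the progenitor genome, the frame in which its
    mutations are called and classified.
    """

    base_reference: Genome
    progenitor_model: MutantModel
    progenitor_genome: Genome
    annotation: GeneAnnotation
    mutants: list[tuple[str, MutantModel]]
    planted_unique: pd.DataFrame  # chrom pos ref alt effect_class


def _codon_context(feat: pd.Series, pos: int, genome: Genome):
    """(codon, index_within_codon, strand) for a position inside a feature."""
    from .core import revcomp

    if feat["strand"] == "+":
        offset = pos - int(feat["start"])
        c_start = int(feat["start"]) + (offset // 3) * 3
        return genome.fetch(feat["chrom"], c_start, c_start + 2), offset % 3, "+"
    offset = int(feat["end"]) - pos
    c_end = int(feat["end"]) - (offset // 3) * 3
    return revcomp(genome.fetch(feat["chrom"], c_end - 2, c_end)), offset % 3, "-"


def _pick_coding_snv(
    rng: np.random.Generator,
    genome: Genome,
    annotation: GeneAnnotation,
    want_synonymous: bool,
    used: set[tuple[str, int]],
) -> PlannedSNV:
    from .core import revcomp

    feats = annotation.records
    for _ in range(20000):
        feat = feats.iloc[int(rng.integers(0, len(feats)))]
        pos = int(rng.integers(int(feat["start"]), int(feat["end"]) + 1))
        if (feat["chrom"], pos) in used:
            continue
        codon, within, strand = _codon_context(feat, pos, genome)
        ref_base = genome.base_at(feat["chrom"], pos)
        alts = [b for b in BASES if b != ref_base]
        rng.shuffle(alts)
        for alt in alts:
            sub = revcomp(alt) if strand == "-" else alt
            mutated = codon[:within] + sub + codon[within + 1 :]
            same = translate_codon(codon) == translate_codon(mutated)
            if same == want_synonymous:
                used.add((feat["chrom"], pos))
                label = "synonymous" if want_synonymous else "nonsynonymous"
                return PlannedSNV(feat["chrom"], pos, ref_base, alt, label)
    raise ValidationError("could not place a coding SNV of the requested class")


def _pick_intergenic_snv(
    rng: np.random.Generator,
    genome: Genome,
    annotation: GeneAnnotation,
    used: set[tuple[str, int]],
) -> PlannedSNV:
    chrom_names = genome.chrom_names
    for _ in range(20000):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        pos = int(rng.integers(1, len(genome.sequences[chrom]) + 1))
        if (chrom, pos) in used or annotation.feature_at(chrom, pos) is not None:
            continue
        ref_base = genome.base_at(chrom, pos)
        alt = [b for b in BASES if b != ref_base][int(rng.integers(0, 3))]
        used.add((chrom, pos))
        return PlannedSNV(chrom, pos, ref_base, alt, "intergenic")
    raise ValidationError("could not place an intergenic SNV")


def make_point_mutation_cohort(seed: int = 42) -> CohortFixture:
    """The packaged cohort: one progenitor, ten mutants, 39 unique point
    mutations (22 nonsynonymous, 8 synonymous, 9 intergenic).

    The progenitor differs from the base reference by six SNVs and two
    small indels, exercising iterative reference refinement. Five of the 39
    mutations recur in a second mutant, exercising cross-mutant
    deduplication; two mutants additionally carry a chromosome disomy.
    """
    rng = np.random.default_rng(seed)
    spec = GenomeSpec(
        chrom_names=("chr1", "chr2", "chr3", "chr4"),
        chrom_lengths=(60000, 50000, 45000, 40000),
        gc_fraction=0.38,
        seed=int(rng.integers(0, 2**31)),
    )
    base = simulate_genome(spec)

    # progenitor: SNVs + small indels relative to the base reference
    used_prog: set[tuple[str, int]] = set()
    prog_snvs = []
    for _ in range(6):
        chrom = spec.chrom_names[int(rng.integers(0, 4))]
        pos = int(rng.integers(100, len(base.sequences[chrom]) - 100))
        if (chrom, pos) in used_prog:
            continue
        used_prog.add((chrom, pos))
        ref_base = base.base_at(chrom, pos)
        alt = [b for b in BASES if b != ref_base][int(rng.integers(0, 3))]
        prog_snvs.append(PlannedSNV(chrom, pos, ref_base, alt))
    ins_pos = int(rng.integers(5000, 10000))
    del_pos = int(rng.integers(20000, 25000))
    prog_indels = [
        PlannedIndel("chr1", ins_pos, "TAG", "insertion"),
        PlannedIndel("chr2", del_pos, base.fetch("chr2", del_pos + 1, del_pos + 2), "deletion"),
    ]
    prog_plan = MutationPlan(snvs=prog_snvs, indels=prog_indels)
    progenitor_model = plant_events(base, prog_plan)
    progenitor = progenitor_model.genome

    annotation = generate_annotation(
        progenitor, n_genes=40, seed=int(rng.integers(0, 2**31))
    )

    used: set[tuple[str, int]] = set()
    planted: list[PlannedSNV] = []
    for effect, count in COHORT_EFFECT_COUNTS.items():
        for _ in range(count):
            if effect == "intergenic":
                planted.append(_pick_intergenic_snv(rng, progenitor, annotation, used))
            else:
                planted.append(
                    _pick_coding_snv(rng, progenitor, annotation, effect == "synonymous", used)
                )
    order = rng.permutation(len(planted))
    assignments: dict[int, list[PlannedSNV]] = {i: [] for i in range(COHORT_N_MUTANTS)}
    for k, idx in enumerate(order):
        assignments[k % COHORT_N_MUTANTS].append(planted[idx])
    shared = [planted[i] for i in order[:COHORT_N_SHARED]]
    for j, snv in enumerate(shared):
        target = (j + 1) % COHORT_N_MUTANTS
        if snv not in assignments[target]:
            assignments[target].append(snv)

    mutants: list[tuple[str, MutantModel]] = []
    for i in range(COHORT_N_MUTANTS):
        plan = MutationPlan(snvs=assignments[i])
        if i == 0:
            plan.disomies = ["chr2"]
        if i == 1:
            plan.disomies = ["chr4"]
        mutants.append((f"mut{i + 1:02d}", plant_events(progenitor, plan)))

    planted_unique = pd.DataFrame(
        [
            {"chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt,
             "effect_class": s.effect_class}
            for s in planted
        ]
    ).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return CohortFixture(
        base_reference=base,
        progenitor_model=progenitor_model,
        progenitor_genome=progenitor,
        annotation=annotation,
        mutants=mutants,
        planted_unique=planted_unique,
    )


# -- fixture serialization -----------------------------------------------


def write_fixtures(
    model: MutantModel,
    annotation: GeneAnnotation,
    out_dir: str | Path,
    reference: Genome | None = None,
    mean_depth: int = 100,
    seed: int = 42,
) -> dict[str, Path]:
    """Write a complete text fixture set for one mutant model.

    Emits the mutant genome FASTA, a dense pileup TSV (noiseless, against
    ``reference`` or the mutant's own genome), the annotation BED, the
    truth JSON, and screen MIC / qPCR Cq tables. Reading the files back
    reproduces the in-memory objects.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fasta",
        "pileup": out / "pileup.tsv",
        "annotation": out / "annotation.bed",
        "truth": out / "truth.json",
        "screen": out / "screen_mic.tsv",
        "qpcr": out / "qpcr_cq.tsv",
    }
    try:
        model.genome.to_fasta(paths["genome"])
        ref = reference if reference is not None else model.genome
        plp = simulate_pileup(model, ref, mean_depth=mean_depth, noise="none", seed=seed)
        plp.to_tsv(paths["pileup"])
        annotation.to_bed(paths["annotation"])
        with open(paths["truth"], "w") as fh:
            json.dump(
                {"events": [t.to_dict() for t in model.truth]},
                fh, indent=1, sort_keys=True,
            )
        screen, _ = make_screen_fixture(seed=seed)
        screen.to_csv(paths["screen"], sep="\t", index=False)
        make_qpcr_fixture(seed=seed).to_csv(paths["qpcr"], sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"failed writing fixture to {exc.filename}: {exc}") from exc
    return paths
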
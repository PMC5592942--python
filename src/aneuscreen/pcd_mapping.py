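"""PCR-mediated chromosomal deletion (PCD) design and causal-interval
inference.

A PCD construct truncates a chromosome at an insertion site: everything
distal (telomere-proximal) to the site is lost. The construct carries, in
order, a homology arm ending at the insertion position, a selection
cassette (kanMX by default), and a synthetic telomere seed (six repeats of
CCCCAA) that nucleates a new telomere. The pieces are joined by overlap
fusion PCR, so the inner primers carry 30-base 5' tails identical to the
terminus of the neighbouring segment.

Mapping logic: truncating at position p deletes [p, telomere], so a
truncation that reverts the phenotype proves the causal element lies at or
distal to p, while one that retains it proves the element was not removed.
A monotone panel of staggered truncations therefore brackets the causal
element between the most distal reverting position and the most proximal
retaining position beyond it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GeneAnnotation, Genome, Interval, ValidationError, revcomp

TELOMERE_MOTIF = "CCCCAA"


@dataclass(frozen=True)
class PCDParams:
    """Construct-design parameters.

    arm_len
        Homology-arm length, 300-600 bp (450 default, the midpoint).
    fusion_tail_len
        Length of the 5' fusion tails on the inner primers (30 bases).
    primer_core_len
        Annealing portion of each primer.
    telomere_motif / telomere_repeats
        The telomere seed is ``motif * repeats`` (CCCCAA x 6 = 36 nt).
    """

    arm_len: int = 450
    fusion_tail_len: int = 30
    primer_core_len: int = 20
    telomere_motif: str = TELOMERE_MOTIF
    telomere_repeats: int = 6
    cassette_id: str = "kanMX"

    def __post_init__(self) -> None:
        if not 300 <= self.arm_len <= 600:
            raise ValidationError("arm_len must be within 300-600 bp")
        if self.fusion_tail_len < 1 or self.primer_core_len < 1:
            raise ValidationError("tail and primer lengths must be >= 1")

    @property
    def telomere_seed(self) -> str:
        return self.telomere_motif * self.telomere_repeats


def load_cassette(name: str = "kanMX") -> str:
    """Packaged selection-cassette sequence (a synthetic stand-in with the
    kanMX role; substitute any cassette FASTA via ``design_construct``)."""
    ref = resources.files("aneuscreen.data") / "kanmx_cassette_synthetic.fasta"
    lines = ref.read_text().splitlines()
    return "".join(l.strip() for l in lines if not l.startswith(">"))


@dataclass
class PCDConstruct:
    """A designed truncation construct and its primer set.

    ``insertion_pos`` is the last retained chromosome position; the arm is
    the genome subsequence ``[insertion_pos - arm_len + 1, insertion_pos]``
    on the + strand. Primers are written 5'->3'; inner primers carry their
    fusion tails at the 5' end.
    """

    chrom: str
    insertion_pos: int
    arm_seq: str
    arm_start: int
    arm_end: int
    cassette_seq: str
    telomere_seed_seq: str
    primers: dict[str, str] = field(default_factory=dict)

    @property
    def full_sequence(self) -> str:
        return self.arm_seq + self.cassette_seq + self.telomere_seed_seq


def design_construct(
    genome: Genome,
    chrom: str,
    insertion_pos: int,
    params: PCDParams = PCDParams(),
    cassette_seq: str | None = None,
) -> PCDConstruct:
    """Design the truncation construct for one insertion site.

    Emits four primers: the arm forward primer, the arm reverse primer
    (5'-tailed with the reverse complement of the cassette's first 30
    bases), the cassette forward primer (5'-tailed with the arm's last 30
    bases), and the cassette reverse primer (5'-tailed with the reverse
    complement of the telomere seed).
    """
    if cassette_seq is None:
        cassette_seq = load_cassette(params.cassette_id)
    arm_start = insertion_pos - params.arm_len + 1
    if arm_start < 1:
        raise ValidationError(
            f"insertion at {chrom}:{insertion_pos} leaves no room for a "
            f"{params.arm_len} bp homology arm"
        )
    arm = genome.fetch(chrom, arm_start, insertion_pos)
    tail = params.fusion_tail_len
    core = params.primer_core_len
    if len(cassette_seq) < tail + core:
        raise ValidationError("cassette shorter than tail + primer core")
    seed = params.telomere_seed
    primers = {
        "arm_fwd": arm[:core],
        "arm_rev": revcomp(cassette_seq[:tail]) + revcomp(arm[-core:]),
        "cassette_fwd": arm[-tail:] + cassette_seq[:core],
        "cassette_rev": revcomp(seed) + revcomp(cassette_seq[-core:]),
    }
    return PCDConstruct(
        chrom=chrom,
        insertion_pos=insertion_pos,
        arm_seq=arm,
        arm_start=arm_start,
        arm_end=insertion_pos,
        cassette_seq=cassette_seq,
        telomere_seed_seq=seed,
        primers=primers,
    )


def plan_tiling(region: Interval, target_spacing_bp: int = 50_000) -> list[int]:
    """Evenly staggered insertion positions across a region.

    Both region ends are always included; interior positions divide the
    region into the number of near-equal gaps whose size is closest to
    ``target_spacing_bp``. A region shorter than the spacing degrades to
    just its two endpoints.
    """
    if target_spacing_bp < 1:
        raise ValidationError("target_spacing_bp must be >= 1")
    lower, upper = region.lower, region.upper
    span = upper - lower
    n_gaps = max(1, int(round(span / target_spacing_bp)))
    raw = np.linspace(lower, upper, n_gaps + 1)
    positions = sorted(set(int(round(v)) for v in raw))
    return positions


@dataclass(frozen=True)
class PCDResult:
    """Phenotype outcome of one truncation strain.

    ``phenotype_reverted`` is True when the truncation abolished the
    tolerance gain (the strain fell back to the euploid progenitor's
    phenotype), i.e. the deleted distal segment contained the causal
    element.
    """

    strain_id: str
    insertion_pos: int
    phenotype_reverted: bool


@dataclass
class InferredInterval:
    interval: Interval
    censored: bool  # True when no retaining truncation bounds the interval


def infer_interval(results: list[PCDResult], region: Interval) -> InferredInterval:
    """Bracket the causal element from a monotone truncation panel.

    Returns ``[max(reverting positions), min(retaining positions above
    it))``; with no retaining position beyond the reverting ones the upper
    bound is censored at the region end. A non-monotone pattern (a
    retaining truncation proximal to a reverting one) is an error naming
    the conflicting strains; no reverting truncation at all is an error
    prompting a more proximal search.
    """
    if not results:
        raise ValidationError("empty truncation panel")
    reverting = [r for r in results if r.phenotype_reverted]
    retaining = [r for r in results if not r.phenotype_reverted]
    if not reverting:
        raise ValidationError(
            "no truncation reverted the phenotype; the causal element lies "
            "proximal to the panel — extend truncations toward the centromere"
        )
    lower = max(r.insertion_pos for r in reverting)
    conflicts = [r for r in retaining if r.insertion_pos <= lower]
    if conflicts:
        rev_ids = [r.strain_id for r in reverting if r.insertion_pos >= min(
            c.insertion_pos for c in conflicts)]
        raise ValidationError(
            "non-monotone phenotype pattern (possible epistasis or strain "
            f"mislabeling): retaining {[c.strain_id for c in conflicts]} lie "
            f"proximal to reverting {rev_ids}"
        )
    above = [r.insertion_pos for r in retaining if r.insertion_pos > lower]
    if above:
        return InferredInterval(Interval(region.chrom, lower, min(above)), censored=False)
    return InferredInterval(Interval(region.chrom, lower, region.upper), censored=True)


def genes_in_interval(
    annotation: GeneAnnotation, interval: Interval
) -> dict[str, pd.DataFrame]:
    """Features overlapping the interval (any overlap), split by type."""
    df = annotation.features_on(interval.chrom)
    hits = df[
        (df["end"] >= interval.lower) & (df["start"] < interval.upper)
    ].reset_index(drop=True)
    return {
        "gene": hits[hits["feature_type"] == "gene"].reset_index(drop=True),
        "dubious_ORF": hits[hits["feature_type"] == "dubious_ORF"].reset_index(drop=True),
    }


def constructs_to_frames(
    constructs: list[PCDConstruct],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(construct table, primer table) ready for TSV output."""
    cons = pd.DataFrame(
        [
            {
                "chrom": c.chrom, "insertion_pos": c.insertion_pos,
                "arm_start": c.arm_start, "arm_end": c.arm_end,
                "construct_length": len(c.full_sequence),
            }
            for c in constructs
        ]
    )
    primers = pd.DataFrame(
        [
            {
                "insertion_pos": c.insertion_pos, "primer": name,
                "sequence_5to3": seq,
                "tail": ("fusion" if name in ("arm_rev", "cassette_fwd")
                         else "telomere_seed" if name == "cassette_rev" else "none"),
            }
            for c in constructs
            for name, seq in c.primers.items()
        ]
    )
    return cons, primers
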
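"""Core sequence containers shared by every stage of the pipeline.

Coordinates are 1-based and inclusive throughout the in-memory model, the
same convention as SAM/mpileup. The only place 0-based half-open
coordinates appear is BED serialization, where the conversion happens at
the file boundary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved per base)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """One-letter amino acid (or ``*``) for a DNA codon, standard code."""
    return str(Seq(codon).translate())


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass
class Genome:
    """A haploid genome: chromosome name -> uppercase A/C/G/T string.

    Positions are 1-based inclusive; ``fetch(chrom, start, end)`` returns
    the bases at ``start..end``.
    """

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValidationError(f"chromosome {name!r} is empty")
            stripped = set(seq) - set(BASES)
            if stripped:
                raise ValidationError(
                    f"chromosome {name!r} contains non-ACGT characters: "
                    f"{sorted(stripped)[:5]}"
                )

    @property
    def chrom_names(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Bases at 1-based inclusive ``start..end`` of ``chrom``."""
        seq = self.sequences[chrom]
        if not (1 <= start <= end <= len(seq)):
            raise ValidationError(
                f"{chrom}:{start}-{end} outside 1..{len(seq)}"
            )
        return seq[start - 1 : end]

    def base_at(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Genome) and self.sequences == other.sequences

    # -- FASTA I/O --------------------------------------------------------

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        seqs = {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")
        }
        if not seqs:
            raise ValidationError(f"no sequences found in {path}")
        return cls(seqs)


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval: ``lower`` 1-based inclusive, ``upper``
    exclusive."""

    chrom: str
    lower: int
    upper: int

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValidationError(
                f"interval lower ({self.lower}) must be < upper ({self.upper})"
            )

    @property
    def length(self) -> int:
        return self.upper - self.lower

    def contains(self, pos: int) -> bool:
        return self.lower <= pos < self.upper

    def overlaps_feature(self, start: int, end: int) -> bool:
        """Any-overlap against a 1-based inclusive feature span."""
        return end >= self.lower and start < self.upper


ANNOTATION_COLUMNS = ["feature_id", "chrom", "start", "end", "strand", "feature_type"]
FEATURE_TYPES = {"gene", "dubious_ORF"}


@dataclass
class GeneAnnotation:
    """Gene/dubious-ORF features, 1-based inclusive coordinates.

    ``records`` is a DataFrame with columns
    ``feature_id chrom start end strand feature_type``. Coding features
    (both ``gene`` and ``dubious_ORF`` — dubious ORFs are still ORFs) must
    have length divisible by 3 and may not overlap another feature on the
    same strand.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = set(ANNOTATION_COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"annotation missing columns {sorted(missing)}")
        if (df["start"] > df["end"]).any():
            raise ValidationError("annotation has start > end")
        bad_type = set(df["feature_type"]) - FEATURE_TYPES
        if bad_type:
            raise ValidationError(f"unknown feature types {sorted(bad_type)}")
        lengths = df["end"] - df["start"] + 1
        if (lengths % 3 != 0).any():
            bad = df.loc[lengths % 3 != 0, "feature_id"].iloc[0]
            raise ValidationError(f"feature {bad} length not a codon multiple")
        for (chrom, strand), grp in df.groupby(["chrom", "strand"], sort=False):
            g = grp.sort_values("start")
            if (g["start"].values[1:] <= g["end"].values[:-1]).any():
                raise ValidationError(
                    f"overlapping same-strand features on {chrom}{strand}"
                )
        self.records = df.reset_index(drop=True)

    def features_on(self, chrom: str) -> pd.DataFrame:
        return self.records[self.records["chrom"] == chrom]

    def feature_at(self, chrom: str, pos: int) -> pd.Series | None:
        """The feature containing ``pos``, or None if intergenic."""
        df = self.features_on(chrom)
        hit = df[(df["start"] <= pos) & (df["end"] >= pos)]
        if hit.empty:
            return None
        return hit.iloc[0]

    # -- BED I/O (0-based half-open on disk) ------------------------------

    def to_bed(self, path: str | Path) -> None:
        out = self.records.copy()
        out["bed_start"] = out["start"] - 1
        out["score"] = 0
        out[
            ["chrom", "bed_start", "end", "feature_id", "score", "strand", "feature_type"]
        ].to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path: str | Path) -> "GeneAnnotation":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "bed_start", "end", "feature_id", "score", "strand", "feature_type"],
        )
        df["start"] = df["bed_start"] + 1
        return cls(df[ANNOTATION_COLUMNS].copy())


def _as_dict(obj) -> dict:
    return dataclasses.asdict(obj)
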
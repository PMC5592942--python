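"""Per-site pileup container and its on-disk dialects.

The native dialect is a dense TSV with one row per reference site:

    chrom  pos  ref  depth  A  C  G  T  ins  del

``pos`` is 1-based. ``ins`` / ``del`` are ``.`` or ``SEQ:COUNT``, recording
reads that show an insertion of SEQ immediately after this site, or a
deletion of SEQ (the reference bases at pos+1..pos+len) immediately after
this site. Sites inside a homozygous deletion keep their spanning-read
depth but have zero base counts, so ``depth == A+C+G+T`` holds everywhere
except under a deletion, where ``depth`` counts the spanning reads.

An adapter for the 6-column ``samtools mpileup`` text format is provided so
externally aligned data can enter the pipeline without touching BAMs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BASES, Genome, ValidationError

_BASE_TO_IDX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _BASE_TO_IDX[ord(_b)] = _i


def base_indices(ref: np.ndarray) -> np.ndarray:
    """Map an ``S1`` byte array of bases to indices into ``ACGT``."""
    return _BASE_TO_IDX[ref.view(np.uint8)]


@dataclass
class ChromPileup:
    """Dense per-site pileup for one chromosome.

    ``counts`` has shape ``(4, n)`` in A,C,G,T order. ``ins``/``dels`` map a
    1-based anchor position to ``(sequence, read_count)``.
    """

    ref: np.ndarray          # dtype S1, length n
    depth: np.ndarray        # int64, length n
    counts: np.ndarray       # int64, shape (4, n)
    ins: dict[int, tuple[str, int]] = field(default_factory=dict)
    dels: dict[int, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.ref)
        if self.depth.shape != (n,) or self.counts.shape != (4, n):
            raise ValidationError("pileup array shapes disagree")

    @property
    def n_sites(self) -> int:
        return len(self.ref)


@dataclass
class Pileup:
    """Pileups for a whole genome, keyed by chromosome name."""

    chroms: dict[str, ChromPileup]

    @property
    def total_sites(self) -> int:
        return sum(c.n_sites for c in self.chroms.values())

    @property
    def total_depth(self) -> int:
        return int(sum(c.depth.sum() for c in self.chroms.values()))

    def mean_depth(self) -> float:
        return self.total_depth / self.total_sites

    # -- native TSV dialect ----------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\tdepth\tA\tC\tG\tT\tins\tdel\n")
            for chrom, cp in self.chroms.items():
                n = cp.n_sites
                ins_col = np.full(n, ".", dtype=object)
                del_col = np.full(n, ".", dtype=object)
                for pos, (seq, count) in cp.ins.items():
                    ins_col[pos - 1] = f"{seq}:{count}"
                for pos, (seq, count) in cp.dels.items():
                    del_col[pos - 1] = f"{seq}:{count}"
                df = pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": np.arange(1, n + 1),
                        "ref": cp.ref.astype("U1"),
                        "depth": cp.depth,
                        "A": cp.counts[0],
                        "C": cp.counts[1],
                        "G": cp.counts[2],
                        "T": cp.counts[3],
                        "ins": ins_col,
                        "del": del_col,
                    }
                )
                df.to_csv(fh, sep="\t", header=False, index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Pileup":
        df = pd.read_csv(path, sep="\t", dtype={"ref": str, "ins": str, "del": str})
        chroms: dict[str, ChromPileup] = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            grp = grp.sort_values("pos")
            n = int(grp["pos"].max())
            if len(grp) != n or grp["pos"].iloc[0] != 1:
                raise ValidationError(f"pileup TSV for {chrom} is not dense from 1")
            cp = ChromPileup(
                ref=grp["ref"].to_numpy(dtype="S1"),
                depth=grp["depth"].to_numpy(dtype=np.int64),
                counts=np.vstack(
                    [grp[b].to_numpy(dtype=np.int64) for b in BASES]
                ),
            )
            for col, store in (("ins", cp.ins), ("del", cp.dels)):
                tagged = grp[grp[col] != "."]
                for pos, tok in zip(tagged["pos"], tagged[col]):
                    seq, count = tok.rsplit(":", 1)
                    store[int(pos)] = (seq, int(count))
            chroms[str(chrom)] = cp
        return cls(chroms)


_MPILEUP_INDEL = re.compile(r"[+-](\d+)")


def _parse_mpileup_bases(bases: str, ref_base: str) -> tuple[dict[str, int], dict[str, int], dict[str, int]]:
    """Decode one mpileup base-string into base counts and indel counts.

    Handles ``^X`` (read start + mapping quality), ``$`` (read end),
    ``.``/``,`` (reference match), ``*`` (deletion placeholder) and
    ``+N``/``-N`` indel tokens per the mpileup format.
    """
    counts = {b: 0 for b in BASES}
    ins: dict[str, int] = {}
    dels: dict[str, int] = {}
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            m = _MPILEUP_INDEL.match(bases, i)
            if not m:
                raise ValidationError(f"bad indel token at {bases[i:i+8]!r}")
            ln = int(m.group(1))
            seq = bases[m.end() : m.end() + ln].upper()
            target = ins if c == "+" else dels
            target[seq] = target.get(seq, 0) + 1
            i = m.end() + ln
            continue
        if c in ".,":
            counts[ref_base] += 1
        elif c.upper() in counts:
            counts[c.upper()] += 1
        # '*' (deletion placeholder) and N add no base evidence
        i += 1
    return counts, ins, dels


def pileup_from_mpileup(path: str | Path, reference: Genome) -> Pileup:
    """Adapt ``samtools mpileup`` 6-column text output to a dense Pileup.

    Sites absent from the file are zero-filled against ``reference``. Only
    the majority insertion/deletion sequence at a site is retained, matching
    the single-alternate-allele model of the caller.
    """
    chroms = {
        name: ChromPileup(
            ref=np.frombuffer(seq.encode(), dtype="S1").copy(),
            depth=np.zeros(len(seq), dtype=np.int64),
            counts=np.zeros((4, len(seq)), dtype=np.int64),
        )
        for name, seq in reference.sequences.items()
    }
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, pos, ref_base, depth, bases = (
                parts[0],
                int(parts[1]),
                parts[2].upper(),
                int(parts[3]),
                parts[4] if len(parts) > 4 else "",
            )
            if chrom not in chroms:
                raise ValidationError(f"mpileup chromosome {chrom!r} not in reference")
            cp = chroms[chrom]
            expected = cp.ref[pos - 1].decode()
            if ref_base != "N" and ref_base != expected:
                raise ValidationError(
                    f"mpileup reference base {ref_base} at {chrom}:{pos} "
                    f"disagrees with genome base {expected}"
                )
            counts, ins, dels = _parse_mpileup_bases(bases, expected)
            for j, b in enumerate(BASES):
                cp.counts[j, pos - 1] = counts[b]
            cp.depth[pos - 1] = depth
            if ins:
                seq = max(ins, key=ins.get)
                cp.ins[pos] = (seq, ins[seq])
            if dels:
                seq = max(dels, key=dels.get)
                cp.dels[pos] = (seq, dels[seq])
    return Pileup(chroms)
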
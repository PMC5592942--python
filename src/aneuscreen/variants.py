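"""Allele-fraction variant calling and iterative reference refinement.

The decision rule for haploid strains: a site is called a difference from
the reference when a single non-reference allele is supported by at least
``min_fraction`` (default 90%, boundary inclusive) of the reads, with at
least ``min_depth`` reads covering the site. Progenitor-specific reference
genomes are built by iterating call -> integrate (up to ``max_cycles``
rounds, default 10) until a round finds no further differences; mutant
mutations are then called against the refined progenitor reference.

Variant tables are plain pandas DataFrames with columns
``chrom pos ref alt type fraction depth`` (``VARIANT_COLUMNS``), using
anchored VCF-style alleles for indels (insertion: ref=anchor base,
alt=anchor+inserted; deletion: ref=anchor+deleted, alt=anchor base).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .core import BASES, GeneAnnotation, Genome, ValidationError, revcomp, translate_codon
from .pileup import Pileup, base_indices


@dataclass(frozen=True)
class CallerParams:
    """Thresholds for difference calling.

    min_fraction
        Minimum read fraction supporting a single alternate allele
        (inclusive). 0.90 is the screen's published rule.
    min_depth
        Minimum covering reads; guards against high-fraction calls from a
        handful of reads. Configurable; not part of the published rule.
    max_indel_bp
        Indels longer than this are ignored (only small indels are modeled).
    """

    min_fraction: float = 0.90
    min_depth: int = 10
    max_indel_bp: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.min_fraction <= 1:
            raise ValidationError("min_fraction must be in (0, 1]")
        if self.min_depth < 1:
            raise ValidationError("min_depth must be >= 1")


VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "type", "fraction", "depth"]

EFFECT_CLASSES = ("nonsynonymous", "synonymous", "intergenic", "not_applicable")


def empty_variant_set() -> pd.DataFrame:
    return pd.DataFrame(columns=VARIANT_COLUMNS)


def call_differences(
    pileup: Pileup, reference: Genome, params: CallerParams = CallerParams()
) -> pd.DataFrame:
    """Call SNV/indel differences between a pileup and its reference.

    A site is called iff ``depth >= min_depth`` and a single non-reference
    allele reaches ``min_fraction`` of the depth (inclusive). Each alternate
    allele is evaluated independently; at a fraction threshold above 0.5 at
    most one can qualify. Returns a variant DataFrame sorted by
    (chrom, pos).
    """
    rows: list[dict] = []
    for chrom, cp in pileup.chroms.items():
        if chrom not in reference.sequences:
            raise ValidationError(f"pileup chromosome {chrom!r} not in reference")
        seq = reference.sequences[chrom]
        ref_arr = np.frombuffer(seq.encode(), dtype="S1")
        if cp.n_sites != len(seq):
            raise ValidationError(
                f"pileup for {chrom} has {cp.n_sites} sites, reference has {len(seq)}"
            )
        mismatch = cp.ref != ref_arr
        if mismatch.any():
            pos = int(np.flatnonzero(mismatch)[0]) + 1
            raise ValidationError(
                f"pileup reference base at {chrom}:{pos} disagrees with genome"
            )
        depth = cp.depth
        ref_idx = base_indices(ref_arr)
        alt_counts = cp.counts.copy()
        alt_counts[ref_idx, np.arange(cp.n_sites)] = -1
        best = np.argmax(alt_counts, axis=0)
        best_count = alt_counts[best, np.arange(cp.n_sites)]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(depth > 0, best_count / np.maximum(depth, 1), 0.0)
        called = (depth >= params.min_depth) & (best_count > 0) & (
            frac >= params.min_fraction
        )
        for i in np.flatnonzero(called):
            rows.append(
                {
                    "chrom": chrom,
                    "pos": int(i) + 1,
                    "ref": seq[i],
                    "alt": BASES[best[i]],
                    "type": "snv",
                    "fraction": float(frac[i]),
                    "depth": int(depth[i]),
                }
            )
        for anchor, (ins_seq, count) in cp.ins.items():
            d = int(depth[anchor - 1])
            if d < params.min_depth or len(ins_seq) > params.max_indel_bp:
                continue
            if count / d >= params.min_fraction:
                base = seq[anchor - 1]
                rows.append(
                    {
                        "chrom": chrom,
                        "pos": anchor,
                        "ref": base,
                        "alt": base + ins_seq,
                        "type": "insertion",
                        "fraction": count / d,
                        "depth": d,
                    }
                )
        for anchor, (del_seq, count) in cp.dels.items():
            d = int(depth[anchor - 1])
            if d < params.min_depth or len(del_seq) > params.max_indel_bp:
                continue
            if count / d >= params.min_fraction:
                base = seq[anchor - 1]
                expected = seq[anchor : anchor + len(del_seq)]
                if expected != del_seq:
                    raise ValidationError(
                        f"deletion at {chrom}:{anchor} records {del_seq} but the "
                        f"reference reads {expected}"
                    )
                rows.append(
                    {
                        "chrom": chrom,
                        "pos": anchor,
                        "ref": base + del_seq,
                        "alt": base,
                        "type": "deletion",
                        "fraction": count / d,
                        "depth": d,
                    }
                )
    if not rows:
        return empty_variant_set()
    out = pd.DataFrame(rows)
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


# -- variant integration -------------------------------------------------


def _variant_footprint(row: Mapping) -> tuple[int, int]:
    """1-based inclusive span of reference bases a variant rewrites.

    Insertions occupy no reference base beyond their anchor; the anchor is
    included so two indels cannot share it.
    """
    pos = int(row["pos"])
    if row["type"] == "deletion":
        return pos, pos + len(row["ref"]) - 1
    return pos, pos


class CoordinateMap:
    """Old-reference -> new-reference position mapping for one integration
    round. Deleted positions map to ``None``."""

    def __init__(self, shifts: dict[str, np.ndarray], deleted: dict[str, np.ndarray]):
        self._shifts = shifts      # per chrom: int64 array, index = old pos (1-based)
        self._deleted = deleted    # per chrom: bool array

    @classmethod
    def identity(cls, genome: Genome) -> "CoordinateMap":
        return cls(
            {c: np.zeros(n + 1, dtype=np.int64) for c, n in genome.lengths.items()},
            {c: np.zeros(n + 1, dtype=bool) for c, n in genome.lengths.items()},
        )

    def map(self, chrom: str, pos: int) -> int | None:
        if self._deleted[chrom][pos]:
            return None
        return pos + int(self._shifts[chrom][pos])

    def __call__(self, chrom: str, pos: int) -> int | None:
        return self.map(chrom, pos)


class ComposedMap:
    """Composition of per-cycle coordinate maps (old base -> final)."""

    def __init__(self, maps: list[CoordinateMap]):
        self.maps = maps

    def map(self, chrom: str, pos: int) -> int | None:
        for m in self.maps:
            pos = m.map(chrom, pos)
            if pos is None:
                return None
        return pos

    def __call__(self, chrom: str, pos: int) -> int | None:
        return self.map(chrom, pos)


def integrate_variants(
    reference: Genome, variants: pd.DataFrame
) -> tuple[Genome, CoordinateMap]:
    """Substitute called variants into the reference genome.

    SNVs are replaced in place; indels are applied right-to-left per
    chromosome so earlier coordinates stay valid and the result is
    independent of input order. Overlapping variants are rejected.
    """
    shifts: dict[str, np.ndarray] = {}
    deleted: dict[str, np.ndarray] = {}
    new_seqs: dict[str, str] = {}
    for chrom, seq in reference.sequences.items():
        n = len(seq)
        vs = (
            variants[variants["chrom"] == chrom]
            if len(variants)
            else variants
        )
        if len(vs) == 0:
            new_seqs[chrom] = seq
            shifts[chrom] = np.zeros(n + 1, dtype=np.int64)
            deleted[chrom] = np.zeros(n + 1, dtype=bool)
            continue
        vs = vs.sort_values("pos", kind="stable")
        spans = [ _variant_footprint(r) for _, r in vs.iterrows() ]
        positions = vs["pos"].tolist()
        if len(set(positions)) != len(positions):
            dup = [p for p in positions if positions.count(p) > 1][0]
            raise ValidationError(f"colliding variants at {chrom}:{dup}")
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValidationError(
                    f"overlapping variants on {chrom}: {s1}-{e1} and {s2}-{e2}"
                )
        delta = np.zeros(n + 2, dtype=np.int64)
        is_del = np.zeros(n + 1, dtype=bool)
        chars = list(seq)
        # right-to-left so indel edits never invalidate pending coordinates
        for _, row in vs.iloc[::-1].iterrows():
            pos = int(row["pos"])
            if row["type"] == "snv":
                if chars[pos - 1] != row["ref"]:
                    raise ValidationError(
                        f"reference base at {chrom}:{pos} is {chars[pos - 1]}, "
                        f"variant expects {row['ref']}"
                    )
                chars[pos - 1] = row["alt"]
            elif row["type"] == "insertion":
                ins = row["alt"][1:]
                chars[pos:pos] = list(ins)
                if pos + 1 <= n:
                    delta[pos + 1] += len(ins)
            elif row["type"] == "deletion":
                ln = len(row["ref"]) - 1
                if seq[pos - 1 : pos + ln] != row["ref"]:
                    raise ValidationError(
                        f"deletion ref mismatch at {chrom}:{pos}"
                    )
                del chars[pos : pos + ln]
                is_del[pos + 1 : pos + ln + 1] = True
                if pos + ln + 1 <= n:
                    delta[pos + ln + 1] -= ln
            else:
                raise ValidationError(f"unknown variant type {row['type']!r}")
        new_seqs[chrom] = "".join(chars)
        shifts[chrom] = np.cumsum(delta[: n + 1])
        deleted[chrom] = is_del
    return Genome(new_seqs), CoordinateMap(shifts, deleted)


# -- iterative refinement ------------------------------------------------


@dataclass
class RefinedReference:
    """Result of iterative progenitor-reference refinement."""

    genome: Genome
    cycles_run: int
    converged: bool
    variants_per_cycle: list[int]
    coordinate_map: ComposedMap

    def report(self) -> dict:
        return {
            "cycles_run": self.cycles_run,
            "converged": self.converged,
            "variants_per_cycle": self.variants_per_cycle,
        }


def refine_reference(
    base: Genome,
    pileup_provider: Callable[[Genome], Pileup],
    max_cycles: int = 10,
    params: CallerParams = CallerParams(),
) -> RefinedReference:
    """Iteratively fold progenitor differences into the base reference.

    Each cycle calls differences between the progenitor's pileup (produced
    by ``pileup_provider`` against the current genome) and that genome,
    then integrates them. Stops when a cycle yields zero variants
    (converged) or after ``max_cycles`` cycles.
    """
    genome = base
    maps: list[CoordinateMap] = []
    counts: list[int] = []
    converged = False
    cycles = 0
    for _ in range(max_cycles):
        cycles += 1
        plp = pileup_provider(genome)
        vs = call_differences(plp, genome, params)
        counts.append(len(vs))
        if len(vs) == 0:
            converged = True
            break
        genome, cmap = integrate_variants(genome, vs)
        maps.append(cmap)
    return RefinedReference(
        genome=genome,
        cycles_run=cycles,
        converged=converged,
        variants_per_cycle=counts,
        coordinate_map=ComposedMap(maps),
    )


# -- mutant calling and effect classification ----------------------------


def call_mutations(
    mutant_pileup: Pileup,
    progenitor_reference: Genome,
    params: CallerParams = CallerParams(),
    mutant_id: str = "",
) -> pd.DataFrame:
    """Call a mutant's mutations against its refined progenitor reference.

    Same decision rule as :func:`call_differences`; adds ``mutant_id`` and
    an unset ``effect`` column pending :func:`classify_effects`.
    """
    calls = call_differences(mutant_pileup, progenitor_reference, params)
    calls["mutant_id"] = mutant_id
    calls["effect"] = ""
    return calls


def classify_effect(
    call: Mapping, annotation: GeneAnnotation, genome: Genome
) -> str:
    """Coding effect of a single SNV call: nonsynonymous / synonymous /
    intergenic (indels return ``not_applicable``).

    The affected codon is read from the feature's strand and translated
    with the standard genetic code; identical amino acids mean synonymous.
    """
    if call["type"] != "snv":
        return "not_applicable"
    chrom, pos = call["chrom"], int(call["pos"])
    feat = annotation.feature_at(chrom, pos)
    if feat is None:
        return "intergenic"
    length = int(feat["end"]) - int(feat["start"]) + 1
    if length % 3 != 0:
        raise ValidationError(
            f"feature {feat['feature_id']} length {length} is not a codon multiple"
        )
    if feat["strand"] == "+":
        offset = pos - int(feat["start"])
    else:
        offset = int(feat["end"]) - pos
    codon_idx = offset // 3
    within = offset % 3
    if feat["strand"] == "+":
        c_start = int(feat["start"]) + codon_idx * 3
        codon = genome.fetch(chrom, c_start, c_start + 2)
        mutated = codon[:within] + call["alt"] + codon[within + 1 :]
    else:
        c_end = int(feat["end"]) - codon_idx * 3
        codon = revcomp(genome.fetch(chrom, c_end - 2, c_end))
        mutated = codon[:within] + revcomp(call["alt"]) + codon[within + 1 :]
    return "synonymous" if translate_codon(codon) == translate_codon(mutated) else "nonsynonymous"


def classify_effects(
    calls: pd.DataFrame, annotation: GeneAnnotation, genome: Genome
) -> pd.DataFrame:
    """Fill the ``effect`` column of a mutation-call table."""
    out = calls.copy()
    out["effect"] = [
        classify_effect(row, annotation, genome) for _, row in calls.iterrows()
    ]
    return out


def unique_mutations(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Deduplicate calls across mutants on (chrom, pos, ref, alt).

    Returns the unique table (first occurrence kept) and per-effect-class
    counts; recurrent mutations shared by several mutants count once.
    """
    if len(cohort) == 0:
        return cohort.copy(), {}
    unique = cohort.drop_duplicates(subset=["chrom", "pos", "ref", "alt"]).reset_index(
        drop=True
    )
    counts = (
        unique["effect"].value_counts().to_dict() if "effect" in unique else {}
    )
    return unique, counts
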
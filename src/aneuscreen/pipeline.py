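"""End-to-end orchestration: simulate -> refine -> call -> ploidy ->
summarize, plus the truncation-mapping loop, with a single config object
and deterministic, re-runnable outputs.

Every stage consumes in-memory objects or files produced by earlier
stages; a fixed config + seed reproduces outputs byte for byte (floats
are rounded before serialization and JSON keys are sorted).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import ploidy as pl
from . import synthetic_data as sd
from .core import GeneAnnotation, Genome, Interval, ValidationError
from .pcd_mapping import (
    InferredInterval,
    PCDParams,
    PCDResult,
    genes_in_interval,
    infer_interval,
    plan_tiling,
)
from .phenotype import QPCRParams, ScreenParams
from .variants import (
    CallerParams,
    call_mutations,
    classify_effects,
    refine_reference,
    unique_mutations,
)

log = logging.getLogger("aneuscreen")


@dataclass
class RunConfig:
    """All knobs for a pipeline run; every default that has a published
    value keeps it (0.90 fraction, 10 cycles, 1.0/0.5 mM screen deltas,
    30-base fusion tails, CCCCAA x 6 telomere seed, ~50 kb tiling)."""

    seed: int = 42
    out_dir: str = "aneuscreen_out"
    mean_depth: int = 100
    error_rate: float = 0.0
    noise: str = "none"
    max_cycles: int = 10
    focal_chrom: str = "chr2"
    focal_arm_start: int | None = None
    write_plots: bool = False
    caller: CallerParams = field(default_factory=CallerParams)
    ploidy: pl.PloidyParams = field(default_factory=pl.PloidyParams)
    pcd: PCDParams = field(default_factory=PCDParams)
    screen: ScreenParams = field(default_factory=ScreenParams)
    qpcr: QPCRParams = field(default_factory=QPCRParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        blocks = {
            "caller": CallerParams, "ploidy": pl.PloidyParams, "pcd": PCDParams,
            "screen": ScreenParams, "qpcr": QPCRParams,
        }
        kwargs: dict = {}
        for key, value in raw.items():
            if key in blocks:
                kwargs[key] = blocks[key](**(value or {}))
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _write_json(payload: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(_round_floats(payload), fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_screen_analysis(config: RunConfig) -> dict:
    """Run the full synthetic screen analysis and write its report.

    Generates the packaged cohort (one progenitor, ten mutants, 39 unique
    point mutations, two chromosome disomies), refines the progenitor
    reference against the base genome, calls and classifies each mutant's
    mutations, makes per-chromosome ploidy calls from windowed coverage,
    summarizes arm disomy across the cohort, and scores recovery against
    the planted truth. Returns the report dict (also written as JSON +
    TSVs under ``config.out_dir``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        log.info("stage=simulate seed=%d", config.seed)
        fixture = sd.make_point_mutation_cohort(seed=config.seed)

        stage = "refine"
        log.info("stage=refine max_cycles=%d min_fraction=%.2f",
                 config.max_cycles, config.caller.min_fraction)

        def provider(genome: Genome):
            return sd.simulate_pileup(
                fixture.progenitor_model, genome,
                mean_depth=config.mean_depth, error_rate=config.error_rate,
                noise=config.noise, seed=config.seed,
            )

        refined = refine_reference(
            fixture.base_reference, provider,
            max_cycles=config.max_cycles, params=config.caller,
        )
        _write_json(refined.report(), out / "refinement.json")

        stage = "call"
        all_calls = []
        ploidy_calls: list[tuple[str, str, pl.PloidyCall]] = []
        ploidy_rows = []
        for i, (mutant_id, model) in enumerate(fixture.mutants):
            plp = sd.simulate_pileup(
                model, refined.genome,
                mean_depth=config.mean_depth, error_rate=config.error_rate,
                noise=config.noise, seed=config.seed + 1 + i,
            )
            calls = call_mutations(plp, refined.genome, config.caller, mutant_id)
            calls = classify_effects(calls, fixture.annotation, refined.genome)
            all_calls.append(calls)

            track = pl.scale_track(pl.windowed_coverage(plp, config.ploidy))
            genome_calls = pl.classify_genome(track, config.ploidy)
            for chrom, call in genome_calls.items():
                ploidy_rows.append(
                    {"mutant_id": mutant_id, "chrom": chrom,
                     "copy_number": call.copy_number, "scope": call.scope,
                     "breakpoint": call.breakpoint if call.breakpoint else ".",
                     "fraction": round(call.duplicated_fraction, 4)}
                )
            focal = genome_calls[config.focal_chrom]
            ploidy_calls.append((mutant_id, "cohort", focal))
            if config.write_plots:
                pl.plot_coverage(track, str(out / f"coverage_{mutant_id}.png"),
                                 title=mutant_id)

        cohort = pd.concat(all_calls, ignore_index=True)
        cohort.to_csv(out / "mutation_calls.tsv", sep="\t", index=False)
        pd.DataFrame(ploidy_rows).to_csv(out / "ploidy_calls.tsv", sep="\t", index=False)

        stage = "summarize"
        unique, class_counts = unique_mutations(cohort)
        unique.to_csv(out / "unique_mutations.tsv", sep="\t", index=False)
        focal_len = len(refined.genome.sequences[config.focal_chrom])
        arm_start = config.focal_arm_start or focal_len // 2 + 1
        focal_arm = Interval(config.focal_chrom, arm_start, focal_len + 1)
        summary = pl.summarize_cohort(ploidy_calls, focal_arm)
        summary.to_csv(out / "cohort_summary.tsv", sep="\t", index=False)

        stage = "score"
        recovery = score_recovery(fixture, cohort)
        report = {
            "seed": config.seed,
            "n_mutants": len(fixture.mutants),
            "refinement": refined.report(),
            "unique_mutations": len(unique),
            "unique_by_effect": class_counts,
            "cohort_summary": summary.to_dict(orient="records"),
            "recovery": recovery,
        }
        _write_json(report, out / "screen_report.json")
        return report
    except Exception as exc:
        raise RuntimeError(f"screen analysis failed at stage {stage!r}: {exc}") from exc


def score_recovery(fixture: sd.CohortFixture, cohort_calls: pd.DataFrame) -> dict:
    """Sensitivity/precision of SNV calls and disomy recovery vs truth."""
    truth_keys = set()
    disomy_truth = set()
    for mutant_id, model in fixture.mutants:
        for t in model.truth:
            if t.event_type == "snv":
                truth_keys.add((mutant_id, t.chrom, t.start, t.alt))
            elif t.event_type == "disomy":
                disomy_truth.add((mutant_id, t.chrom))
    snv_calls = cohort_calls[cohort_calls["type"] == "snv"]
    called_keys = {
        (r["mutant_id"], r["chrom"], int(r["pos"]), r["alt"])
        for _, r in snv_calls.iterrows()
    }
    tp = len(truth_keys & called_keys)
    return {
        "snv_sensitivity": tp / len(truth_keys) if truth_keys else None,
        "snv_precision": tp / len(called_keys) if called_keys else None,
        "n_planted_snv_instances": len(truth_keys),
        "n_called_snv_instances": len(called_keys),
        "n_planted_disomies": len(disomy_truth),
    }


def run_pcd_mapping(
    results: pd.DataFrame,
    region: Interval,
    annotation: GeneAnnotation | None = None,
    out_dir: str | Path = "pcd_out",
    params: PCDParams = PCDParams(),
    next_spacing_bp: int | None = None,
) -> dict:
    """Infer the causal interval from a truncation-panel results table.

    ``results`` has columns ``strain insertion_pos reverted``. Emits the
    inferred interval (with censoring flag), its length, overlapping
    annotation features, and a tiling plan for the next refinement round.
    """
    if results.empty:
        raise ValidationError("empty truncation results table")
    panel = [
        PCDResult(str(r["strain"]), int(r["insertion_pos"]), bool(r["reverted"]))
        for _, r in results.iterrows()
    ]
    inferred = infer_interval(panel, region)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    interval = inferred.interval
    spacing = next_spacing_bp or max(1000, interval.length // 5)
    next_plan = plan_tiling(interval, spacing)
    report = {
        "interval": {"chrom": interval.chrom, "lower": interval.lower,
                     "upper": interval.upper, "length_bp": interval.length,
                     "length_kb_nearest": int(round(interval.length / 1000))},
        "censored_upper": inferred.censored,
        "next_tiling_positions": next_plan,
    }
    if annotation is not None:
        hits = genes_in_interval(annotation, interval)
        report["genes"] = hits["gene"]["feature_id"].tolist()
        report["dubious_ORFs"] = hits["dubious_ORF"]["feature_id"].tolist()
    _write_json(report, out / "interval.json")
    pd.DataFrame({"insertion_pos": next_plan}).to_csv(
        out / "next_tiling.tsv", sep="\t", index=False
    )
    return report
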
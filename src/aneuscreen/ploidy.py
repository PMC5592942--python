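"""Coverage-based detection of whole-chromosome disomy and terminal
segmental duplications.

Per-site depths are averaged in fixed windows (1 kb by default), scaled to
the genome-wide per-site mean, and compared against a euploid baseline.
The baseline defaults to the median of per-chromosome median scaled values
rather than the genome mean, because a duplicated chromosome large enough
to matter also inflates the mean it would be judged against; the
genome-mean scaling is kept for display, matching the usual whole-genome
coverage plot convention.

Segmental duplications are modeled as a single step in the scaled
coverage: the changepoint minimizing the total squared error of a
two-level piecewise-constant fit, accepted only when the two segments
round to different integer copy numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Genome, Interval, ValidationError
from .pileup import Pileup

TRACK_COLUMNS = ["chrom", "start", "end", "n_bp", "mean_depth", "scaled"]


@dataclass
class PloidyParams:
    """Tunable knobs for coverage-based copy-number calling.

    window_bp
        Window width; the final window of a chromosome keeps its true
        (shorter) length.
    baseline_estimator
        ``median_of_chrom_medians`` (robust to a few aneuploid
        chromosomes) or ``genome_mean``.
    whole_chrom_fraction
        Fraction of a chromosome's windows that must share a modal copy
        number > 1 for a whole-chromosome call.
    min_segment_windows
        Minimum windows per segment for a segmental call.
    cn_max
        Copy numbers are clipped to [1, cn_max].
    low_conf_band
        Scaled values within this distance of a half-integer multiple of
        the baseline are flagged low-confidence.
    """

    window_bp: int = 1000
    baseline_estimator: str = "median_of_chrom_medians"
    whole_chrom_fraction: float = 0.95
    min_segment_windows: int = 10
    cn_max: int = 4
    low_conf_band: float = 0.15

    def __post_init__(self) -> None:
        if self.window_bp < 1:
            raise ValidationError("window_bp must be >= 1")
        if not 0 < self.whole_chrom_fraction <= 1:
            raise ValidationError("whole_chrom_fraction must be in (0, 1]")
        if self.baseline_estimator not in ("median_of_chrom_medians", "genome_mean"):
            raise ValidationError(
                f"unknown baseline_estimator {self.baseline_estimator!r}"
            )


@dataclass
class CoverageTrack:
    """Windowed coverage: DataFrame ``chrom start end n_bp mean_depth
    scaled`` (start/end 1-based inclusive) plus the genome-wide per-site
    mean depth. ``scaled`` is NaN until :func:`scale_track` runs."""

    windows: pd.DataFrame
    genome_mean_depth: float

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.windows[self.windows["chrom"] == chrom]

    @property
    def is_scaled(self) -> bool:
        return not self.windows["scaled"].isna().any()


@dataclass
class PloidyCall:
    """Copy-number call for one chromosome.

    For segmental calls, ``breakpoint`` is the left edge (1-based start)
    of the right-hand segment of the two-level fit, and
    ``dup_start``/``dup_end`` bound the duplicated segment.
    """

    chrom: str
    copy_number: int
    scope: str  # "euploid" | "whole" | "segmental"
    breakpoint: int | None = None
    duplicated_span_bp: int = 0
    duplicated_fraction: float = 0.0
    dup_start: int | None = None
    dup_end: int | None = None
    low_confidence: bool = False

    def covers(self, arm: Interval) -> bool:
        """Does this call place the whole focal arm at copy number >= 2?"""
        if self.copy_number < 2:
            return False
        if self.scope == "whole":
            return True
        if self.scope == "segmental" and self.dup_start is not None:
            return self.dup_start <= arm.lower and self.dup_end >= arm.upper - 1
        return False


def windowed_coverage(pileup: Pileup, params: PloidyParams = PloidyParams()) -> CoverageTrack:
    """Tile each chromosome with fixed windows and average per-site depth.

    Windows tile without gaps or overlap; a final partial window is kept
    with its true length. A window wider than the chromosome degrades to a
    single chromosome-spanning window.
    """
    frames = []
    for chrom, cp in pileup.chroms.items():
        n = cp.n_sites
        starts0 = np.arange(0, n, params.window_bp)
        ends0 = np.minimum(starts0 + params.window_bp, n)
        sums = np.add.reduceat(cp.depth, starts0)
        lengths = ends0 - starts0
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts0 + 1,
                    "end": ends0,
                    "n_bp": lengths,
                    "mean_depth": sums / lengths,
                    "scaled": np.nan,
                }
            )
        )
    windows = pd.concat(frames, ignore_index=True)
    return CoverageTrack(windows=windows, genome_mean_depth=pileup.mean_depth())


def coverage_track_from_table(df: pd.DataFrame) -> CoverageTrack:
    """Build a track from a precomputed ``chrom start end mean_depth``
    table (1-based inclusive coordinates)."""
    out = df.copy()
    out["n_bp"] = out["end"] - out["start"] + 1
    out["scaled"] = np.nan
    gmean = float((out["mean_depth"] * out["n_bp"]).sum() / out["n_bp"].sum())
    return CoverageTrack(windows=out[TRACK_COLUMNS], genome_mean_depth=gmean)


def scale_track(track: CoverageTrack) -> CoverageTrack:
    """Scale window means to the genome-wide per-site mean depth.

    The length-weighted mean of the scaled values is exactly 1 by
    construction.
    """
    if track.genome_mean_depth <= 0:
        raise ValidationError("genome mean depth is zero; cannot scale")
    windows = track.windows.copy()
    windows["scaled"] = windows["mean_depth"] / track.genome_mean_depth
    return CoverageTrack(windows=windows, genome_mean_depth=track.genome_mean_depth)


def euploid_baseline(track: CoverageTrack, params: PloidyParams = PloidyParams()) -> float:
    """Scaled-coverage level of a single-copy region."""
    if params.baseline_estimator == "genome_mean":
        return 1.0
    medians = track.windows.groupby("chrom", sort=False)["scaled"].median()
    return float(medians.median())


def _rounded_cn(scaled: np.ndarray, baseline: float, params: PloidyParams) -> np.ndarray:
    ratio = scaled / baseline
    return np.clip(np.rint(ratio).astype(int), 1, params.cn_max)


def _is_low_confidence(mean_ratio: float, params: PloidyParams) -> bool:
    return abs(mean_ratio - (np.floor(mean_ratio) + 0.5)) <= params.low_conf_band


def detect_segmental(
    track: CoverageTrack,
    chrom: str,
    params: PloidyParams = PloidyParams(),
    baseline: float | None = None,
) -> PloidyCall:
    """Single-changepoint scan for a segmental duplication on ``chrom``.

    Minimizes the total squared error of a two-level piecewise-constant
    fit over all split points leaving at least ``min_segment_windows``
    windows per side (leftmost split on ties). A segmental call is
    returned only when the two segment means round to different copy
    numbers; otherwise the chromosome falls back to a whole/euploid call
    from its modal rounded copy number.
    """
    if not track.is_scaled:
        raise ValidationError("track must be scaled before classification")
    if baseline is None:
        baseline = euploid_baseline(track, params)
    win = track.for_chrom(chrom)
    x = win["scaled"].to_numpy()
    n = len(x)
    chrom_len = int(win["end"].max())

    def fallback() -> PloidyCall:
        cn = _rounded_cn(x, baseline, params)
        modal = int(np.bincount(cn).argmax())
        if modal > 1:
            return PloidyCall(chrom, modal, "whole", duplicated_span_bp=chrom_len,
                              duplicated_fraction=1.0, dup_start=1, dup_end=chrom_len)
        return PloidyCall(chrom, 1, "euploid")

    if n < 2 * params.min_segment_windows:
        return fallback()
    c1 = np.cumsum(x)
    c2 = np.cumsum(x * x)
    total1, total2 = c1[-1], c2[-1]
    ks = np.arange(params.min_segment_windows, n - params.min_segment_windows + 1)
    left1, left2 = c1[ks - 1], c2[ks - 1]
    sse = (left2 - left1**2 / ks) + (
        (total2 - left2) - (total1 - left1) ** 2 / (n - ks)
    )
    k = int(ks[np.argmin(sse)])  # np.argmin takes the first (leftmost) minimum
    mean_left = float(c1[k - 1] / k)
    mean_right = float((total1 - c1[k - 1]) / (n - k))
    cn_left = int(np.clip(round(mean_left / baseline), 1, params.cn_max))
    cn_right = int(np.clip(round(mean_right / baseline), 1, params.cn_max))
    if cn_left == cn_right:
        return fallback()
    breakpoint_pos = int(win["start"].to_numpy()[k])
    n_bp = win["n_bp"].to_numpy()
    if cn_right > cn_left:
        dup_start, dup_end = breakpoint_pos, chrom_len
        span = int(n_bp[k:].sum())
        cn = cn_right
        ratio = mean_right / baseline
    else:
        dup_start, dup_end = 1, breakpoint_pos - 1
        span = int(n_bp[:k].sum())
        cn = cn_left
        ratio = mean_left / baseline
    return PloidyCall(
        chrom=chrom,
        copy_number=cn,
        scope="segmental",
        breakpoint=breakpoint_pos,
        duplicated_span_bp=span,
        duplicated_fraction=span / chrom_len,
        dup_start=dup_start,
        dup_end=dup_end,
        low_confidence=_is_low_confidence(ratio, params),
    )


def classify_ploidy(
    track: CoverageTrack, chrom: str, params: PloidyParams = PloidyParams()
) -> PloidyCall:
    """Classify one chromosome as euploid, whole-chromosome duplicated, or
    segmentally duplicated.

    A whole-chromosome call requires at least ``whole_chrom_fraction`` of
    the windows to share a modal rounded copy number above 1; otherwise a
    single-changepoint segmental scan decides; otherwise euploid.
    """
    if not track.is_scaled:
        raise ValidationError("track must be scaled before classification")
    baseline = euploid_baseline(track, params)
    win = track.for_chrom(chrom)
    if win.empty:
        raise ValidationError(f"no windows for chromosome {chrom!r}")
    x = win["scaled"].to_numpy()
    chrom_len = int(win["end"].max())
    cn = _rounded_cn(x, baseline, params)
    modal = int(np.bincount(cn).argmax())
    modal_frac = float((cn == modal).mean())
    if modal > 1 and modal_frac >= params.whole_chrom_fraction:
        ratio = float(np.mean(x) / baseline)
        return PloidyCall(
            chrom, modal, "whole",
            duplicated_span_bp=chrom_len, duplicated_fraction=1.0,
            dup_start=1, dup_end=chrom_len,
            low_confidence=_is_low_confidence(ratio, params),
        )
    if len(x) < 2 * params.min_segment_windows:
        if len(x) < params.min_segment_windows:
            warnings.warn(
                f"{chrom}: only {len(x)} windows; segmental detection skipped",
                stacklevel=2,
            )
        if modal > 1:
            return PloidyCall(chrom, modal, "whole", duplicated_span_bp=chrom_len,
                              duplicated_fraction=1.0, dup_start=1, dup_end=chrom_len)
        return PloidyCall(chrom, 1, "euploid")
    return detect_segmental(track, chrom, params, baseline=baseline)


def classify_genome(
    track: CoverageTrack, params: PloidyParams = PloidyParams()
) -> dict[str, PloidyCall]:
    """Ploidy call for every chromosome in the track."""
    return {
        chrom: classify_ploidy(track, chrom, params)
        for chrom in track.windows["chrom"].unique()
    }


def calls_to_frame(calls: dict[str, PloidyCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom, "copy_number": c.copy_number, "scope": c.scope,
                "breakpoint": c.breakpoint if c.breakpoint is not None else ".",
                "span_bp": c.duplicated_span_bp,
                "fraction": round(c.duplicated_fraction, 4),
            }
            for c in calls.values()
        ]
    )


def summarize_cohort(
    calls: list[tuple[str, str, PloidyCall]], focal_arm: Interval
) -> pd.DataFrame:
    """Per-group fraction of mutants disomic for the focal chromosome arm.

    ``calls`` holds ``(mutant_id, group, call-for-the-focal-chromosome)``.
    A mutant counts as arm-disomic when its call covers the full focal arm
    at copy number >= 2 — a whole-chromosome disomy or a segmental
    duplication spanning the arm. Percentages are rounded to the nearest
    integer; an ``ALL`` row aggregates the whole screen.
    """
    if not calls:
        raise ValidationError("no calls to summarize")
    df = pd.DataFrame(
        [
            {"mutant_id": m, "group": g, "arm_disomic": call.covers(focal_arm)}
            for m, g, call in calls
        ]
    )
    rows = []
    groups = list(dict.fromkeys(df["group"]))
    for label, sub in [("ALL", df)] + [(g, df[df["group"] == g]) for g in groups]:
        n = len(sub)
        k = int(sub["arm_disomic"].sum())
        rows.append(
            {
                "group": label, "n_mutants": n, "n_arm_disomic": k,
                "fraction_percent": int(round(100 * k / n)) if n else np.nan,
                "undefined": n == 0,
            }
        )
    return pd.DataFrame(rows)


def plot_coverage(track: CoverageTrack, path: str, title: str = "") -> None:
    """Whole-genome scaled-coverage panel, one strip per chromosome."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(track.windows["chrom"].unique())
    fig, axes = plt.subplots(
        1, len(chroms), figsize=(max(8, len(chroms)), 2.2),
        sharey=True, gridspec_kw={"wspace": 0.08},
    )
    if len(chroms) == 1:
        axes = [axes]
    for ax, chrom in zip(axes, chroms):
        win = track.for_chrom(chrom)
        mid = (win["start"] + win["end"]) / 2
        ax.plot(mid / 1000, win["scaled"], ".", ms=1.5, color="tab:blue")
        ax.axhline(1.0, lw=0.5, color="grey")
        ax.axhline(2.0, lw=0.5, ls="--", color="grey")
        ax.set_ylim(0, 3)
        ax.set_xticks([])
        ax.set_xlabel(chrom.replace("chr", ""), fontsize=7)
        ax.spines[["top", "right"]].set_visible(False)
    axes[0].set_ylabel("scaled coverage")
    if title:
        fig.suptitle(title, fontsize=9)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
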
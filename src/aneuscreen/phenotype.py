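"""Screen phenotype arithmetic: MIC determination, the two-stage tolerance
filter, tolerance gains, replicate summaries, and relative qPCR copy
number.

The MIC (minimum inhibitory concentration) of a strain is the lowest
stressor dose at which it cannot grow. The screen keeps a mutant when its
MIC exceeds its progenitor's by at least 1.0 mM in the initial pass and
0.5 mM at confirmation (both thresholds inclusive). Copy number by qPCR
uses the delta-delta-Cq model against a single-copy reference gene with a
configurable amplification efficiency (2.0 = perfect doubling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError


@dataclass
class DoseResponse:
    """Growth outcomes for one strain over an ascending dose grid."""

    strain_id: str
    doses_mM: list[float]
    grew: list[bool]

    def __post_init__(self) -> None:
        if not self.doses_mM:
            raise ValidationError(f"{self.strain_id}: empty dose list")
        if len(self.doses_mM) != len(self.grew):
            raise ValidationError(f"{self.strain_id}: doses and growth flags differ")
        if any(d < 0 for d in self.doses_mM):
            raise ValidationError(f"{self.strain_id}: negative dose")
        if len(set(self.doses_mM)) != len(self.doses_mM):
            raise ValidationError(f"{self.strain_id}: duplicate doses")
        order = np.argsort(self.doses_mM)
        self.doses_mM = [self.doses_mM[i] for i in order]
        self.grew = [bool(self.grew[i]) for i in order]


@dataclass
class MICResult:
    """MIC of one strain; ``censored`` means growth at every tested dose
    (MIC > max dose)."""

    strain_id: str
    mic_mM: float
    censored: bool = False
    warnings: list[str] = field(default_factory=list)


def compute_mic(dr: DoseResponse) -> MICResult:
    """Lowest dose at which the strain could not grow.

    Growth at every dose yields a censored result carrying the maximum
    tested dose. Non-monotone patterns (growth above a no-growth dose)
    still return the literal lowest no-growth dose, with a warning.
    """
    no_growth = [d for d, g in zip(dr.doses_mM, dr.grew) if not g]
    if not no_growth:
        return MICResult(dr.strain_id, max(dr.doses_mM), censored=True)
    mic = min(no_growth)
    warns = []
    if any(g and d > mic for d, g in zip(dr.doses_mM, dr.grew)):
        warns.append(f"non-monotone growth: growth observed above MIC {mic}")
    return MICResult(dr.strain_id, mic, warnings=warns)


def mic_table(growth: pd.DataFrame) -> list[MICResult]:
    """MICs for every strain in a long-format ``strain dose_mM grew``
    table."""
    out = []
    for strain, grp in growth.groupby("strain", sort=False):
        dr = DoseResponse(str(strain), grp["dose_mM"].tolist(),
                          grp["grew"].astype(bool).tolist())
        out.append(compute_mic(dr))
    return out


@dataclass(frozen=True)
class ScreenParams:
    """MIC-gain thresholds of the two screen stages (mM, inclusive)."""

    stage1_delta_mM: float = 1.0
    stage2_delta_mM: float = 0.5

    def __post_init__(self) -> None:
        if self.stage1_delta_mM <= 0 or self.stage2_delta_mM <= 0:
            raise ValidationError("screen deltas must be > 0")

    def delta(self, stage: str) -> float:
        if stage == "initial":
            return self.stage1_delta_mM
        if stage == "confirmation":
            return self.stage2_delta_mM
        raise ValidationError(f"unknown screen stage {stage!r}")


def screen_filter(
    candidates: list[MICResult],
    progenitor: MICResult,
    params: ScreenParams = ScreenParams(),
    stage: str = "confirmation",
) -> list[MICResult]:
    """Keep candidates whose MIC exceeds the progenitor's by at least the
    stage threshold (boundary inclusive).

    A censored candidate (grew at every tested dose) is always kept, with
    a warning noting its MIC is a lower bound.
    """
    if progenitor.censored:
        raise ValidationError(
            f"progenitor {progenitor.strain_id} MIC is censored; extend the dose grid"
        )
    delta = params.delta(stage)
    kept = []
    for cand in candidates:
        if cand.censored:
            flagged = MICResult(
                cand.strain_id, cand.mic_mM, censored=True,
                warnings=cand.warnings + ["MIC censored at max tested dose; kept"],
            )
            kept.append(flagged)
        elif cand.mic_mM - progenitor.mic_mM >= delta:
            kept.append(cand)
    return kept


def tolerance_gain(mutant: MICResult, progenitor: MICResult) -> tuple[float, float]:
    """(MIC gain in mM, gain as percent of the progenitor MIC)."""
    if mutant.censored or progenitor.censored:
        raise ValidationError("tolerance gain undefined for censored MICs")
    if progenitor.mic_mM == 0:
        raise ValidationError("progenitor MIC of 0 mM; percent gain undefined")
    delta = mutant.mic_mM - progenitor.mic_mM
    return delta, 100.0 * delta / progenitor.mic_mM


# -- qPCR relative quantification ----------------------------------------


@dataclass(frozen=True)
class QPCRParams:
    """Delta-delta-Cq model parameters.

    efficiency
        Per-cycle amplification factor (2.0 = perfect doubling).
    """

    efficiency: float = 2.0
    reference_gene: str = "ACT1"
    calibrator: str = "euploid_progenitor"

    def __post_init__(self) -> None:
        if self.efficiency <= 1:
            raise ValidationError("efficiency must be > 1")


def qpcr_relative(
    sample_cq: dict[str, list[float]],
    calibrator_cq: dict[str, list[float]],
    params: QPCRParams = QPCRParams(),
) -> float:
    """Relative target quantity of a sample versus the calibrator.

    ``sample_cq`` / ``calibrator_cq`` map ``"target"`` and ``"reference"``
    to replicate Cq lists. dCq = mean(target) - mean(reference) within
    each sample; the relative quantity is
    ``efficiency ** -(dCq_sample - dCq_calibrator)``.
    """
    for name, d in (("sample", sample_cq), ("calibrator", calibrator_cq)):
        for key in ("target", "reference"):
            if not d.get(key):
                raise ValidationError(f"{name} is missing {key} Cq replicates")
    d_sample = float(np.mean(sample_cq["target"])) - float(np.mean(sample_cq["reference"]))
    d_cal = float(np.mean(calibrator_cq["target"])) - float(np.mean(calibrator_cq["reference"]))
    return params.efficiency ** -(d_sample - d_cal)


def qpcr_from_table(
    cq: pd.DataFrame, target: str, params: QPCRParams = QPCRParams()
) -> pd.DataFrame:
    """Relative quantities for every sample in a ``sample target cq``
    table, against ``params.calibrator``."""
    def split(sample: str) -> dict[str, list[float]]:
        sub = cq[cq["sample"] == sample]
        t = sub[sub["target"] == target]["cq"].tolist()
        r = sub[sub["target"] == params.reference_gene]["cq"].tolist()
        if not r:
            raise ValidationError(
                f"sample {sample!r} has no Cq for reference gene "
                f"{params.reference_gene!r}"
            )
        if not t:
            raise ValidationError(f"sample {sample!r} has no Cq for target {target!r}")
        return {"target": t, "reference": r}

    cal = split(params.calibrator)
    rows = []
    for sample in cq["sample"].unique():
        rows.append(
            {
                "sample": sample, "target": target,
                "relative_quantity": qpcr_relative(split(str(sample)), cal, params),
            }
        )
    return pd.DataFrame(rows)


# -- replicate summaries -------------------------------------------------


@dataclass
class ReplicateSummary:
    mean: float
    ci_low: float
    ci_high: float
    n_biological: int
    ci_defined: bool = True


def summarize_replicates(
    biological: list[float] | None = None,
    technical_reps: list[list[float]] | None = None,
) -> ReplicateSummary:
    """Mean and 95% t-interval over biological replicates.

    Technical replicates, when given, are averaged within each biological
    replicate first; the CI is then ``mean +/- t(0.975, n-1) * sd/sqrt(n)``
    over the n biological means. A single biological replicate returns its
    mean with the CI flagged undefined.
    """
    if technical_reps is not None:
        if biological is not None:
            raise ValidationError("pass either biological means or technical_reps")
        if any(len(reps) == 0 for reps in technical_reps):
            raise ValidationError("empty technical replicate list")
        biological = [float(np.mean(reps)) for reps in technical_reps]
    if not biological:
        raise ValidationError("no replicates supplied")
    n = len(biological)
    mean = float(np.mean(biological))
    if n < 2:
        return ReplicateSummary(mean, math.nan, math.nan, n, ci_defined=False)
    sd = float(np.std(biological, ddof=1))
    half = stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
    return ReplicateSummary(mean, mean - half, mean + half, n)
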
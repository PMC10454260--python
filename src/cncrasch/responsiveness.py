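"""Responsiveness indices for paired (baseline, follow-up) person measures.

Given interval-scale person measures at two timepoints and a reliability
coefficient, this module assembles the standard distribution-based
responsiveness panel used for clinical outcome measures:

* ``SD_pooled = sqrt((sd_bl^2 + sd_fu^2) / 2)`` — equal-n pooled SD of the
  two assessments of the same cohort;
* ``SEM = SD_pooled * sqrt(1 - r)`` — standard error of measurement;
* ``MDC95 = 1.96 * sqrt(2) * SEM`` — minimal detectable change at 95%
  confidence, the smallest individual change beyond measurement error;
* distribution-based MCIDs at 0.20 / 0.33 / 0.50 SD — group-level change
  benchmarks;
* effect size ``(mean_fu - mean_bl) / SD_pooled`` and the standardized
  response mean ``mean(change) / sd(change)``.

Individual change is classified against the MDC95: strictly beyond it in
either direction counts as improvement or decline; a change exactly at the
threshold stays within measurement error (conservative clinical reading).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import InvalidArgumentError, ZeroVarianceError

__all__ = [
    "PairedMeasures",
    "ResponsivenessIndices",
    "ChangeCategory",
    "ChangeRecord",
    "ChangeSummary",
    "pooled_sd",
    "sem",
    "mdc95",
    "distribution_mcid",
    "effect_size",
    "standardized_response_mean",
    "effect_size_ci",
    "classify_change",
    "summarize_change",
    "measure_band",
    "true_change_threshold",
    "compute_indices",
    "indices_from_summary",
    "round_half_up",
]

MCID_FRACTIONS = (0.20, 0.33, 0.50)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (0.625 -> 0.63), as in printed reports."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PairedMeasures:
    """Complete baseline/follow-up measure pairs for one cohort."""

    person_ids: list
    baseline: np.ndarray
    followup: np.ndarray
    spacing_days: float | None = None

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.followup = np.asarray(self.followup, dtype=float)
        n = len(self.person_ids)
        if self.baseline.shape != (n,) or self.followup.shape != (n,):
            raise InvalidArgumentError("ids and measure arrays must align")
        if n < 2:
            raise InvalidArgumentError("need >= 2 paired persons")
        if np.isnan(self.baseline).any() or np.isnan(self.followup).any():
            raise InvalidArgumentError("pairs must be complete (no NaN)")

    @property
    def n(self) -> int:
        return len(self.person_ids)

    @property
    def changes(self) -> np.ndarray:
        return self.followup - self.baseline


@dataclass
class ResponsivenessIndices:
    """The full index panel for one scale version (all logits except ratios)."""

    n: int
    mean_bl: float
    sd_bl: float
    mean_fu: float
    sd_fu: float
    sd_pooled: float
    reliability: float
    sem: float
    mdc95: float
    effect_size: float
    es_ci: tuple[float, float]
    srm: float | None
    mean_change: float
    mcid_020: float
    mcid_033: float
    mcid_050: float

    def to_dict(self, ndigits: int | None = None) -> dict:
        def f(x: float) -> float:
            return round_half_up(x, ndigits) if ndigits is not None else x

        return {
            "n": self.n,
            "mean_baseline": f(self.mean_bl),
            "sd_baseline": f(self.sd_bl),
            "mean_followup": f(self.mean_fu),
            "sd_followup": f(self.sd_fu),
            "SD_pooled": f(self.sd_pooled),
            "Person Separation Reliability": f(self.reliability),
            "Standard error of measurement": f(self.sem),
            "MDC_95": f(self.mdc95),
            "Effect size": f(self.effect_size),
            "Lower 95% CI": f(self.es_ci[0]),
            "Upper 95% CI": f(self.es_ci[1]),
            "Standardized response mean": (
                f(self.srm) if self.srm is not None else None
            ),
            "Mean change": f(self.mean_change),
            "MCID 0.20 SD": f(self.mcid_020),
            "MCID 0.33 SD": f(self.mcid_033),
            "MCID 0.50 SD": f(self.mcid_050),
        }


class ChangeCategory(str, Enum):
    IMPROVED = "improved"
    DECLINED = "declined"
    WITHIN_ERROR = "within_error"


@dataclass
class ChangeRecord:
    """One person's baseline-to-follow-up change and its classification."""

    person_id: object
    baseline: float
    followup: float
    change: float
    category: ChangeCategory


@dataclass
class ChangeSummary:
    n: int
    n_improved: int
    n_declined: int
    n_within_error: int
    records: list[ChangeRecord]

    @property
    def n_beyond_error(self) -> int:
        return self.n_improved + self.n_declined

    def proportions(self) -> dict:
        return {
            "improved": self.n_improved / self.n,
            "declined": self.n_declined / self.n,
            "within_error": self.n_within_error / self.n,
        }


# ---------------------------------------------------------------------------
# elementary indices
# ---------------------------------------------------------------------------


def pooled_sd(sd_bl: float, sd_fu: float) -> float:
    """Equal-n pooled SD of the two assessments of one cohort."""
    if sd_bl <= 0 or sd_fu <= 0:
        raise InvalidArgumentError("standard deviations must be positive")
    return math.sqrt((sd_bl**2 + sd_fu**2) / 2)


def sem(sd_pooled: float, r: float) -> float:
    """Standard error of measurement, ``SD_pooled * sqrt(1 - r)``."""
    if sd_pooled <= 0:
        raise InvalidArgumentError("sd_pooled must be positive")
    if not 0 <= r < 1:
        raise InvalidArgumentError(f"reliability must be in [0, 1), got {r}")
    return sd_pooled * math.sqrt(1 - r)


def mdc95(sem_value: float) -> float:
    """Minimal detectable change at 95% confidence: ``1.96 * sqrt(2) * SEM``."""
    if sem_value < 0:
        raise InvalidArgumentError("sem must be non-negative")
    return 1.96 * math.sqrt(2) * sem_value


def distribution_mcid(sd_pooled: float, k: float) -> float:
    """Distribution-based MCID: fraction ``k`` of the pooled SD."""
    if sd_pooled <= 0:
        raise InvalidArgumentError("sd_pooled must be positive")
    if not 0 < k < 1:
        raise InvalidArgumentError(f"MCID fraction must be in (0, 1), got {k}")
    return k * sd_pooled


def effect_size(mean_bl: float, mean_fu: float, sd_pooled: float) -> float:
    """Group effect size using the pooled SD."""
    if sd_pooled <= 0:
        raise InvalidArgumentError("sd_pooled must be positive")
    return (mean_fu - mean_bl) / sd_pooled


def standardized_response_mean(changes: Sequence[float]) -> float:
    """Mean change divided by the sample SD (n-1) of the change scores."""
    arr = np.asarray(changes, dtype=float)
    if arr.size < 2:
        raise InvalidArgumentError("need >= 2 change scores")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("change scores have zero variance")
    return float(arr.mean() / sd)


def effect_size_ci(es: float, n: int) -> tuple[float, float]:
    """Normal-approximation 95% CI for a paired standardized mean difference."""
    if n < 2:
        raise InvalidArgumentError("need n >= 2")
    half = 1.96 * math.sqrt(1 / n + es**2 / (2 * n))
    return (es - half, es + half)


# ---------------------------------------------------------------------------
# individual change
# ---------------------------------------------------------------------------


def classify_change(change: float, mdc95_value: float) -> ChangeCategory:
    """Classify one change score against the MDC95.

    Strictly beyond the threshold counts; a tie stays within error.
    """
    if mdc95_value <= 0:
        raise InvalidArgumentError("mdc95 must be positive")
    if change > mdc95_value:
        return ChangeCategory.IMPROVED
    if change < -mdc95_value:
        return ChangeCategory.DECLINED
    return ChangeCategory.WITHIN_ERROR


def summarize_change(
    paired: PairedMeasures, mdc95_value: float
) -> ChangeSummary:
    """Per-person classification plus counts by category."""
    records = [
        ChangeRecord(
            person_id=pid,
            baseline=float(bl),
            followup=float(fu),
            change=float(fu - bl),
            category=classify_change(fu - bl, mdc95_value),
        )
        for pid, bl, fu in zip(paired.person_ids, paired.baseline,
                               paired.followup)
    ]
    counts = {c: 0 for c in ChangeCategory}
    for rec in records:
        counts[rec.category] += 1
    return ChangeSummary(
        n=paired.n,
        n_improved=counts[ChangeCategory.IMPROVED],
        n_declined=counts[ChangeCategory.DECLINED],
        n_within_error=counts[ChangeCategory.WITHIN_ERROR],
        records=records,
    )


def measure_band(measure: float, sem_value: float) -> tuple[float, float]:
    """Ability range ``measure +/- SEM`` for bedside interpretation."""
    if sem_value <= 0:
        raise InvalidArgumentError("sem must be positive")
    return (measure - sem_value, measure + sem_value)


def true_change_threshold(
    measure: float, mdc95_value: float, direction: str = "improvement"
) -> float:
    """Measure a patient must reach for change beyond measurement error."""
    if mdc95_value <= 0:
        raise InvalidArgumentError("mdc95 must be positive")
    if direction == "improvement":
        return measure + mdc95_value
    if direction == "decline":
        return measure - mdc95_value
    raise InvalidArgumentError(
        f"direction must be 'improvement' or 'decline', got {direction!r}"
    )


# ---------------------------------------------------------------------------
# panel assembly
# ---------------------------------------------------------------------------


def compute_indices(paired: PairedMeasures, r: float) -> ResponsivenessIndices:
    """Assemble the full responsiveness panel from paired measures."""
    mean_bl = float(paired.baseline.mean())
    mean_fu = float(paired.followup.mean())
    sd_bl = float(paired.baseline.std(ddof=1))
    sd_fu = float(paired.followup.std(ddof=1))
    sp = pooled_sd(sd_bl, sd_fu)
    try:
        srm = standardized_response_mean(paired.changes)
    except ZeroVarianceError:
        srm = None
    return _assemble(
        n=paired.n, mean_bl=mean_bl, sd_bl=sd_bl, mean_fu=mean_fu,
        sd_fu=sd_fu, sd_pooled=sp, r=r, srm=srm,
    )


def indices_from_summary(
    n: int,
    mean_bl: float,
    mean_fu: float,
    sd_pooled: float,
    r: float,
    sd_bl: float | None = None,
    sd_fu: float | None = None,
    srm: float | None = None,
) -> ResponsivenessIndices:
    """Assemble the panel from published summary statistics.

    Used when only the printed cohort summaries (means, pooled SD,
    reliability) are available rather than person-level pairs; the pooled SD
    is taken as given instead of recomputed from rounded SDs.
    """
    return _assemble(
        n=n, mean_bl=mean_bl,
        sd_bl=sd_bl if sd_bl is not None else sd_pooled,
        mean_fu=mean_fu,
        sd_fu=sd_fu if sd_fu is not None else sd_pooled,
        sd_pooled=sd_pooled, r=r, srm=srm,
    )


def _assemble(
    *, n, mean_bl, sd_bl, mean_fu, sd_fu, sd_pooled, r, srm
) -> ResponsivenessIndices:
    s = sem(sd_pooled, r)
    es = effect_size(mean_bl, mean_fu, sd_pooled)
    return ResponsivenessIndices(
        n=n,
        mean_bl=mean_bl,
        sd_bl=sd_bl,
        mean_fu=mean_fu,
        sd_fu=sd_fu,
        sd_pooled=sd_pooled,
        reliability=r,
        sem=s,
        mdc95=mdc95(s),
        effect_size=es,
        es_ci=effect_size_ci(es, n),
        srm=srm,
        mean_change=mean_fu - mean_bl,
        mcid_020=distribution_mcid(sd_pooled, 0.20),
        mcid_033=distribution_mcid(sd_pooled, 0.33),
        mcid_050=distribution_mcid(sd_pooled, 0.50),
    )
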
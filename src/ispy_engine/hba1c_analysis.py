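"""Glycemic-control analysis of longitudinal HbA1c measurements.

HbA1c (glycated hemoglobin, % units) is classified against the clinical
thresholds 5.7% (upper limit of normal) and 6.5% (diabetes criterion). The
analysis cohort consists of patients with a baseline measurement and at least
one on-treatment measurement; for that cohort we count baseline-normal
patients who became elevated on therapy and baseline-elevated patients who
stayed elevated, and compare pCR rates between baseline glycemic classes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .biomarker_eval import fisher_2x2

logger = logging.getLogger(__name__)

#: upper limit of normal HbA1c (%); strictly above is "elevated"
ELEVATED_THRESHOLD = 5.7
#: strictly above this value meets the diabetes criterion
DIABETIC_THRESHOLD = 6.5

PHASES = ("baseline", "on_treatment", "post")


class GlycemicClass(str, Enum):
    NORMAL = "normal"
    ELEVATED = "elevated"
    DIABETIC_RANGE = "diabetic_range"


@dataclass
class HbA1cSeries:
    """Longitudinal HbA1c for one patient: (day, value %, phase) triples."""

    patient_id: str
    measurements: list[tuple[int, float, str]]
    arm: str | None = None

    def __post_init__(self) -> None:
        days = [d for d, _, _ in self.measurements]
        if any(v <= 0 for _, v, _ in self.measurements):
            raise ValueError(f"{self.patient_id}: HbA1c values must be > 0")
        if days != sorted(days):
            raise ValueError(f"{self.patient_id}: measurement days must be "
                             "nondecreasing")
        for _, _, ph in self.measurements:
            if ph not in PHASES:
                raise ValueError(f"{self.patient_id}: unknown phase {ph!r}")

    def values(self, phase: str) -> list[float]:
        return [v for _, v, ph in self.measurements if ph == phase]

    def first_day(self, phase: str) -> int | None:
        days = [d for d, _, ph in self.measurements if ph == phase]
        return min(days) if days else None

    @property
    def baseline(self) -> float | None:
        """Baseline HbA1c: the first baseline-phase measurement."""
        vals = self.values("baseline")
        return vals[0] if vals else None


def classify(value: float) -> GlycemicClass:
    """Classify an HbA1c value (%).

    Boundary convention: exactly 5.7 is normal ("greater than 5.7" wording);
    the diabetic range (> 6.5) is a subset of elevated.
    """
    if value <= 0:
        raise ValueError("HbA1c must be positive")
    if value > DIABETIC_THRESHOLD:
        return GlycemicClass.DIABETIC_RANGE
    if value > ELEVATED_THRESHOLD:
        return GlycemicClass.ELEVATED
    return GlycemicClass.NORMAL


def is_elevated(value: float) -> bool:
    return value > ELEVATED_THRESHOLD


def analysis_cohort(series_list: list[HbA1cSeries]
                    ) -> tuple[list[HbA1cSeries], dict]:
    """Select patients with a baseline and >= 1 on-treatment measurement.

    Returns the qualifying subset and a summary dict with the cohort size and
    the mean/SD of the first on-treatment measurement day.
    """
    cohort = [s for s in series_list
              if s.baseline is not None and s.values("on_treatment")]
    first_days = [s.first_day("on_treatment") for s in cohort]
    summary = {
        "n_input": len(series_list),
        "n_cohort": len(cohort),
        "first_on_treatment_day_mean":
            float(np.mean(first_days)) if first_days else float("nan"),
        "first_on_treatment_day_sd":
            float(np.std(first_days, ddof=1)) if len(first_days) > 1
            else float("nan"),
    }
    logger.info("HbA1c analysis cohort: %d of %d patients qualify",
                summary["n_cohort"], summary["n_input"])
    return cohort, summary


def transition_counts(cohort: list[HbA1cSeries]) -> dict:
    """Count on-treatment glycemic transitions in the analysis cohort.

    A baseline-normal patient "became elevated" if any on-treatment value
    exceeds 5.7; a baseline-elevated patient "stayed elevated" if all
    on-treatment values remain above 5.7.
    """
    n_normal = n_became = n_elev = n_stayed = 0
    for s in cohort:
        base = s.baseline
        on_tx = s.values("on_treatment")
        if base is None or not on_tx:
            raise ValueError(f"{s.patient_id}: not a cohort member")
        if is_elevated(base):
            n_elev += 1
            if all(is_elevated(v) for v in on_tx):
                n_stayed += 1
        else:
            n_normal += 1
            if any(is_elevated(v) for v in on_tx):
                n_became += 1
    return {
        "n_normal_baseline": n_normal,
        "n_became_elevated": n_became,
        "n_elevated_baseline": n_elev,
        "n_stayed_elevated": n_stayed,
    }


def pcr_by_glycemia(cohort: list[HbA1cSeries], pcr: dict[str, int],
                    threshold: float = ELEVATED_THRESHOLD) -> dict:
    """Compare pCR rates between baseline HbA1c <= threshold and > threshold.

    ``pcr`` maps patient id to the binary endpoint. Returns per-class rates,
    counts and the two-sided Fisher exact p-value.
    """
    lo = [s for s in cohort if s.baseline is not None
          and s.baseline <= threshold]
    hi = [s for s in cohort if s.baseline is not None
          and s.baseline > threshold]
    missing = [s.patient_id for s in lo + hi if s.patient_id not in pcr]
    if missing:
        raise ValueError(f"pCR missing for patients: {missing[:5]}")

    def counts(group):
        k = sum(int(pcr[s.patient_id]) for s in group)
        return k, len(group)

    k_lo, n_lo = counts(lo)
    k_hi, n_hi = counts(hi)
    table = np.array([[k_lo, n_lo - k_lo], [k_hi, n_hi - k_hi]])
    return {
        "n_low": n_lo,
        "n_high": n_hi,
        "pcr_rate_low": k_lo / n_lo if n_lo else float("nan"),
        "pcr_rate_high": k_hi / n_hi if n_hi else float("nan"),
        "fisher_p": fisher_2x2(table),
    }
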
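"""DAS28 computation and EULAR response classification.

The 4-variable DAS28-CRP combines 28-joint tender and swollen counts, the
patient global VAS (0-100 mm) and CRP (mg/L):

    DAS28 = 0.56*sqrt(TJC28) + 0.28*sqrt(SJC28) + 0.36*ln(CRP + 1)
            + 0.014*PGA + 0.96

EULAR response at week 26 is read off the standard matrix from the attained
week-26 score and the improvement delta = baseline - week26:

    good:     delta > 1.2 and week26 <= 3.2
    none:     delta <= 0.6, or (delta <= 1.2 and week26 > 5.1)
    moderate: everything else

Ties at the 1.2 improvement boundary fall to the lower category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cohort import ClinicalRecord, Cohort

__all__ = ["CATEGORIES", "DeltaDas", "das28_crp4", "eular_classify",
           "derive_labels"]

CATEGORIES = ("good", "moderate", "none")


@dataclass(frozen=True)
class DeltaDas:
    """Baseline and week-26 DAS28 with their difference (positive = improvement)."""

    baseline_das28: float
    week26_das28: float

    @property
    def delta(self) -> float:
        return self.baseline_das28 - self.week26_das28


def das28_crp4(tjc28: float, sjc28: float, patient_global: float,
               crp: float) -> float:
    """4-variable DAS28-CRP score."""
    if crp < 0:
        raise ValueError("crp must be >= 0")
    if not (0 <= tjc28 <= 28 and 0 <= sjc28 <= 28):
        raise ValueError("joint counts must lie in [0, 28]")
    if not 0 <= patient_global <= 100:
        raise ValueError("patient_global must lie in [0, 100]")
    return (0.56 * math.sqrt(tjc28) + 0.28 * math.sqrt(sjc28)
            + 0.36 * math.log(crp + 1.0) + 0.014 * patient_global + 0.96)


def eular_classify(baseline_das28: float, week26_das28: float) -> str:
    """EULAR three-level response category for a pair of DAS28 scores."""
    if baseline_das28 < 0 or week26_das28 < 0:
        raise ValueError("DAS28 scores must be non-negative")
    delta = baseline_das28 - week26_das28
    if delta > 1.2 and week26_das28 <= 3.2:
        return "good"
    if delta <= 0.6 or (delta <= 1.2 and week26_das28 > 5.1):
        return "none"
    return "moderate"


def _visit_das28(record: ClinicalRecord) -> float:
    if record.das28 is not None:
        return record.das28
    return das28_crp4(record.tjc28, record.sjc28, record.patient_global,
                      record.crp)


def derive_labels(cohort: Cohort, log: list[str] | None = None
                  ) -> dict[str, str]:
    """Classify every patient with both visits; drop (and log) the rest.

    Returns the labels and stores them on the cohort.  Patients already
    labelled keep their label only if it matches the derived one.
    """
    labels: dict[str, str] = {}
    for pid in sorted(cohort.clinical):
        visits = cohort.clinical[pid]
        if "baseline" not in visits or "week26" not in visits:
            if log is not None:
                log.append(f"{pid}: missing visit, not classified")
            continue
        labels[pid] = eular_classify(_visit_das28(visits["baseline"]),
                                     _visit_das28(visits["week26"]))
    cohort.labels = labels
    return labels
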
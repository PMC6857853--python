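"""Patient-level aggregation of per-cell atypia scores.

A patient's cells each carry a score in [0, 1] (0 = most likely normal,
1 = most likely atypical); cells scoring strictly above 0.5 count as atypical.
Three aggregate features summarise a patient:

    percentage of atypical cells = 100 * |{s : s > 0.5}| / n
    mean score of atypical cells = sum of atypical scores / their count
    mean score of all cells      = sum of all scores / n

The mean atypical score is undefined (``None``) for a patient with no
atypical cell; downstream risk stratification treats that as an automatic
negative, since such a patient cannot be high grade under this scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ATYPIA_THRESHOLD",
    "PatientRecord",
    "AggregateFeatures",
    "percentage_atypical",
    "mean_score_all",
    "mean_score_atypical",
    "aggregate_patient",
]

#: Per-cell score strictly above this counts as atypia.
ATYPIA_THRESHOLD = 0.5

#: Diagnostic class labels under the binary grading system (moderate/severe
#: dysplasia and carcinoma-in-situ collapse into HGD).
CLASS_LABELS = ("BNG", "LGD", "HGD", "OSCC")


@dataclass(frozen=True)
class AggregateFeatures:
    percentage_atypical: float  # percent, [0, 100]
    mean_score_all: float  # [0, 1]
    mean_score_atypical: float | None  # (0.5, 1] or None when no atypical cell


@dataclass
class PatientRecord:
    """One patient: id, optional diagnostic class, and per-cell scores."""

    patient_id: str
    scores: list[float] = field(default_factory=list)
    label: str | None = None  # BNG | LGD | HGD | OSCC; optional for prediction
    features: AggregateFeatures | None = None

    def __post_init__(self):
        if self.label is not None and self.label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.label!r}")


def _validate(scores) -> np.ndarray:
    s = np.asarray(scores, dtype=np.float64)
    if s.size == 0:
        raise ValueError("at least one cell score is required")
    if np.any((s < 0.0) | (s > 1.0)):
        raise ValueError("cell scores must lie in [0, 1]")
    return s


def percentage_atypical(scores) -> float:
    """Percent of cells with score strictly above the 0.5 atypia threshold."""
    s = _validate(scores)
    return 100.0 * float(np.count_nonzero(s > ATYPIA_THRESHOLD)) / s.size


def mean_score_all(scores) -> float:
    """Arithmetic mean of all cell scores."""
    s = _validate(scores)
    return float(s.sum() / s.size)


def mean_score_atypical(scores) -> float | None:
    """Mean score over atypical cells; ``None`` when there is none."""
    s = _validate(scores)
    atyp = s[s > ATYPIA_THRESHOLD]
    if atyp.size == 0:
        return None
    return float(atyp.sum() / atyp.size)


def aggregate_patient(record: PatientRecord) -> AggregateFeatures:
    """Compute and attach all three aggregate features for one patient."""
    feats = AggregateFeatures(
        percentage_atypical=percentage_atypical(record.scores),
        mean_score_all=mean_score_all(record.scores),
        mean_score_atypical=mean_score_atypical(record.scores),
    )
    record.features = feats
    return feats
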
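"""Score-to-class mapping, training accuracy, and the subject harness.

A crisp risk score in [0, 1] is mapped to the nearest ACMG class value
(0, 0.25, 0.5, 0.75, 1), giving class boundaries at 0.125, 0.375,
0.625 and 0.875; an exact boundary score resolves to the lower class.
Training accuracy is the fraction of a labelled cohort whose inferred
class equals its recorded class (records for which no rule fires count
as misclassified and are reported separately).

The package ships the twelve published test subjects as a fixture,
together with the risk scores the original systems printed for them;
:func:`run_subject_tests` scores all twelve with both engines for a
side-by-side comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .datamodel import (
    CLASS_LABELS,
    CLASS_VALUES,
    FactorDefinition,
    PatientRecord,
    encode_record,
)
from .fuzzy import RuleBase, UndefinedScoreError, infer, DEFAULT_RESOLUTION
from .nn import NetworkModel, forward

__all__ = [
    "classify_score",
    "CLASS_BOUNDARIES",
    "TrainingAccuracy",
    "training_accuracy",
    "SubjectResult",
    "run_subject_tests",
    "load_test_subjects",
]

#: Upper boundary of each class band except the last (midpoints between
#: consecutive class values).
CLASS_BOUNDARIES = (0.125, 0.375, 0.625, 0.875)


def classify_score(score: float) -> str:
    """Map a risk score to the nearest ACMG class (ties break lower)."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"risk score {score} outside [0, 1]")
    idx = int(np.searchsorted(CLASS_BOUNDARIES, score, side="left"))
    return CLASS_LABELS[idx]


@dataclass(frozen=True)
class TrainingAccuracy:
    """Exact-class agreement of a rule base on a labelled cohort."""

    accuracy: float
    n: int
    n_correct: int
    n_undefined: int  # records for which no rule fired (counted wrong)

    def __float__(self) -> float:
        return self.accuracy


def training_accuracy(
    rulebase: RuleBase,
    cohort: Sequence[PatientRecord],
    catalogue: Sequence[FactorDefinition],
    resolution: int = DEFAULT_RESOLUTION,
) -> TrainingAccuracy:
    """Fraction of the cohort whose infer -> classify class equals its
    recorded class."""
    if not cohort:
        raise ValueError("empty cohort")
    n_correct = 0
    n_undefined = 0
    for patient in cohort:
        if patient.class_label is None:
            raise ValueError(
                f"patient {patient.record_id or '<unnamed>'} is unlabelled"
            )
        try:
            score = infer(rulebase, patient, catalogue, resolution)
        except UndefinedScoreError:
            n_undefined += 1
            continue
        if classify_score(score.value) == patient.class_label:
            n_correct += 1
    return TrainingAccuracy(
        accuracy=n_correct / len(cohort),
        n=len(cohort),
        n_correct=n_correct,
        n_undefined=n_undefined,
    )


@dataclass
class SubjectResult:
    """Both engines' verdicts on one held-out subject."""

    subject_id: str
    expected_class: str
    fuzzy_score: Optional[float]
    fuzzy_class: Optional[str]
    network_score: float
    network_class: str
    fuzzy_error: Optional[str] = None
    reported_fuzzy_score: Optional[float] = None
    reported_network_score: Optional[float] = None

    @property
    def fuzzy_agrees(self) -> bool:
        return self.fuzzy_class == self.expected_class

    @property
    def network_agrees(self) -> bool:
        return self.network_class == self.expected_class


def run_subject_tests(
    rulebase: RuleBase,
    net: NetworkModel,
    subjects: Sequence[PatientRecord],
    catalogue: Sequence[FactorDefinition],
    reported: Optional[dict[str, tuple[float, float]]] = None,
    resolution: int = DEFAULT_RESOLUTION,
) -> list[SubjectResult]:
    """Score every subject with both engines.

    Per-subject engine errors (e.g. no rule fires) are recorded on the
    result rather than aborting the batch.
    """
    results = []
    for i, subject in enumerate(subjects):
        sid = subject.record_id or f"subject-{i + 1}"
        fuzzy_score = fuzzy_class = fuzzy_error = None
        try:
            fuzzy_score = infer(rulebase, subject, catalogue, resolution).value
            fuzzy_class = classify_score(fuzzy_score)
        except UndefinedScoreError as err:
            fuzzy_error = str(err)
        _, clamped = forward(net, encode_record(subject, catalogue))
        rep = (reported or {}).get(sid, (None, None))
        results.append(
            SubjectResult(
                subject_id=sid,
                expected_class=subject.class_label or "Unknown",
                fuzzy_score=fuzzy_score,
                fuzzy_class=fuzzy_class,
                network_score=clamped,
                network_class=classify_score(clamped),
                fuzzy_error=fuzzy_error,
                reported_fuzzy_score=rep[0],
                reported_network_score=rep[1],
            )
        )
    return results


def load_test_subjects() -> tuple[
    list[PatientRecord], dict[str, tuple[float, float]]
]:
    """Load the packaged twelve-subject fixture.

    Returns the subject records and a map from subject id to the
    (fuzzy, network) risk scores the original systems printed for them.
    """
    from .io import read_cohort_csv

    path = resources.files("brcarisk").joinpath("data/test_subjects.csv")
    with resources.as_file(path) as p:
        records, extras = read_cohort_csv(p, return_extras=True)
    reported = {}
    for rec, extra in zip(records, extras):
        fz = extra.get("reported_fuzzy_score")
        nn = extra.get("reported_network_score")
        if fz is not None and nn is not None:
            reported[rec.record_id] = (float(fz), float(nn))
    return records, reported
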
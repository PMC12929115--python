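"""Confidence-weighted accuracy scoring.

Each assigned grade g is converted to a percent accuracy against the eye's true
grade t (0 or 5). The scale applies a mild penalty for uncertainty (a confident
correct call scores higher than a hesitant correct call) and a heavy penalty for
crossing the decision boundary (any wrong-side call scores below 50). Writing
A(g | t=5) for the accuracy of grade g against true edema, the scheme is pinned
by A(5)=100, A(0)=0 and the two interior anchors A(3)=70, A(2)=30; the default
fills the unprinted grades by equal 15-point steps within each side:

    A(. | t=5) = [0, 15, 30, 70, 85, 100]

The no-edema side is the mirror image, A(g | t=0) = A(5-g | t=5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import Diagnosis, GradeRecord, GRADES

__all__ = [
    "ScoringScheme",
    "DEFAULT_SCHEME",
    "weighted_accuracy",
    "accuracy_table",
    "accuracy_long",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Maps (true class, assigned grade) to a weighted accuracy percent.

    Parameters
    ----------
    accuracy_for_true_edema
        Six percentages A(g | t=5) indexed by assigned grade 0..5. Must run
        from 0 to 100, be strictly increasing, keep the printed interior
        anchors A(3)=70 and A(2)=30, and keep the boundary-crossing drop
        A(3)-A(2) strictly larger than every within-side step (the two-tier
        penalty structure).
    """

    accuracy_for_true_edema: tuple[float, ...] = (0.0, 15.0, 30.0, 70.0, 85.0, 100.0)

    def __post_init__(self) -> None:
        a = tuple(float(x) for x in self.accuracy_for_true_edema)
        object.__setattr__(self, "accuracy_for_true_edema", a)
        if len(a) != 6:
            raise ValueError("scheme needs exactly 6 values for grades 0..5")
        if a[0] != 0.0 or a[5] != 100.0:
            raise ValueError("scheme endpoints must be A(0)=0 and A(5)=100")
        if a[2] != 30.0 or a[3] != 70.0:
            raise ValueError("scheme must keep the interior anchors A(2)=30, A(3)=70")
        if any(a[i + 1] <= a[i] for i in range(5)):
            raise ValueError("scheme must be strictly increasing in assigned grade")
        boundary = a[3] - a[2]
        side_steps = (a[1] - a[0], a[2] - a[1], a[4] - a[3], a[5] - a[4])
        if any(boundary <= step for step in side_steps):
            raise ValueError(
                "boundary-crossing drop must exceed every within-side step "
                f"(boundary {boundary}, steps {side_steps})"
            )

    @property
    def accuracy_for_true_no_edema(self) -> tuple[float, ...]:
        """A(g | t=0) = A(5-g | t=5), the mirror of the edema column."""
        return tuple(reversed(self.accuracy_for_true_edema))

    def accuracy(self, grade: int, true_grade: int) -> float:
        if grade not in GRADES:
            raise ValueError(f"grade must be in {{0..5}}, got {grade!r}")
        if true_grade == 5:
            return self.accuracy_for_true_edema[grade]
        if true_grade == 0:
            return self.accuracy_for_true_edema[5 - grade]
        raise ValueError(f"true grade must be 0 or 5, got {true_grade!r}")


DEFAULT_SCHEME = ScoringScheme()


def weighted_accuracy(
    grade: int, diagnosis: Diagnosis, scheme: ScoringScheme = DEFAULT_SCHEME
) -> float:
    """Weighted accuracy percent of an assigned grade for a true diagnosis.

    >>> weighted_accuracy(3, Diagnosis.ODE)
    70.0
    >>> weighted_accuracy(2, Diagnosis.ODE)
    30.0
    """
    return scheme.accuracy(grade, diagnosis.true_grade)


def accuracy_long(
    records: Iterable[GradeRecord], scheme: ScoringScheme = DEFAULT_SCHEME
) -> pd.DataFrame:
    """Long-format DataFrame with one row per record plus its accuracy percent.

    Columns: subject_id, eye, diagnosis, grader_id, modality, grade, accuracy.
    This is the input format of the mixed-ANOVA stage.
    """
    rows = [
        {
            "subject_id": r.subject_id,
            "eye": r.eye.value,
            "diagnosis": r.diagnosis.value,
            "grader_id": r.grader_id,
            "modality": r.modality.value,
            "grade": r.grade,
            "accuracy": scheme.accuracy(r.grade, r.diagnosis.true_grade),
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "eye",
            "diagnosis",
            "grader_id",
            "modality",
            "grade",
            "accuracy",
        ],
    )


def accuracy_table(
    records: Sequence[GradeRecord],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    pool_graders: bool = False,
) -> pd.DataFrame:
    """Mean weighted accuracy per (diagnosis, modality, grader) cell.

    Returns a DataFrame indexed by (diagnosis, modality, grader) — or
    (diagnosis, modality) with ``pool_graders`` — with columns ``mean`` (percent),
    ``se`` (sample SD / sqrt(n); NaN when n < 2) and ``n``. Grader-pooled means
    average the two graders' cell means rather than pooling raw records, so each
    grader carries equal weight. Cells with no records are simply absent.
    """
    if len(records) == 0:
        raise ValueError("accuracy_table requires at least one record")
    df = accuracy_long(records, scheme)
    grouped = df.groupby(["diagnosis", "modality", "grader_id"])["accuracy"]
    table = grouped.agg(mean="mean", sd="std", n="count")
    table["se"] = table.pop("sd") / np.sqrt(table["n"])
    table = table[["mean", "se", "n"]]
    if not pool_graders:
        return table
    pooled = table.reset_index().groupby(["diagnosis", "modality"]).agg(
        mean=("mean", "mean"), se=("se", lambda s: np.sqrt(np.sum(s**2)) / len(s)),
        n=("n", "sum"),
    )
    return pooled
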
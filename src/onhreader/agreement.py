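"""Interrater exact-agreement proportions.

Two graders rate the same eyes under the same modality conditions on the six
point scale; agreement in a (diagnosis, modality) cell is the proportion of
eyes for which both gave the identical integer grade. Raw agreement is used
deliberately (no chance correction): it is insensitive to accuracy, so two
graders agreeing on a wrong grade still count as agreeing. A secondary
"boundary" statistic counts agreement on the side of the edema/no-edema
boundary (grades 0-2 vs 3-5) instead of the exact grade.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .core import GradeRecord

__all__ = ["AgreementTable", "pairwise_agreement"]


@dataclass(frozen=True)
class AgreementTable:
    """Per-(diagnosis, modality) agreement proportions between two graders.

    ``table`` has columns ``proportion`` (exact-grade agreement), ``boundary``
    (same-side agreement) and ``n_pairs``. ``excluded`` counts (eye, modality)
    observations graded by only one of the two graders and therefore dropped.
    """

    grader_a: str
    grader_b: str
    table: pd.DataFrame
    excluded: int


def pairwise_agreement(
    records: Sequence[GradeRecord], grader_a: str, grader_b: str
) -> AgreementTable:
    """Exact-agreement proportion per (diagnosis, modality) for two graders.

    Records are matched on (subject, eye, modality); each matched pair scores 1
    when the two grades are identical and 0 otherwise, and the cell proportion
    is the mean. Symmetric in grader order. Raises if a requested grader has no
    records or no matched pairs exist at all.
    """
    if grader_a == grader_b:
        raise ValueError("agreement needs two distinct graders")
    by_key: dict[tuple, dict[str, GradeRecord]] = {}
    for rec in records:
        if rec.grader_id not in (grader_a, grader_b):
            continue
        key = (rec.subject_id, rec.eye.value, rec.modality.value)
        by_key.setdefault(key, {})[rec.grader_id] = rec

    rows = []
    excluded = 0
    for pair in by_key.values():
        if len(pair) < 2:
            excluded += 1
            continue
        ra, rb = pair[grader_a], pair[grader_b]
        rows.append(
            {
                "diagnosis": ra.diagnosis.value,
                "modality": ra.modality.value,
                "agree": int(ra.grade == rb.grade),
                "agree_boundary": int((ra.grade >= 3) == (rb.grade >= 3)),
            }
        )
    if not rows:
        raise ValueError(f"no matched pairs between graders {grader_a!r} and {grader_b!r}")
    df = pd.DataFrame(rows)
    table = df.groupby(["diagnosis", "modality"]).agg(
        proportion=("agree", "mean"),
        boundary=("agree_boundary", "mean"),
        n_pairs=("agree", "count"),
    )
    return AgreementTable(grader_a=grader_a, grader_b=grader_b, table=table, excluded=excluded)
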
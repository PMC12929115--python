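"""Confidence binning and chi-square independence analysis of grading confidence.

The 0-5 grade encodes both a diagnosis and its certainty, so grades fold onto a
three-level confidence scale independent of which side of the boundary they sit
on: grades 0 and 5 are "definite" calls (high confidence), 1 and 4 "likely"
(medium), 2 and 3 "maybe" (low). Chi-square tests of independence between the
confidence level and a second factor (imaging modality, diagnosis or grader)
show whether, e.g., multimodal image sets shift graders toward definite calls.
Standardized Pearson residuals (O-E)/sqrt(E) localise which cells drive a
significant association; |r| > 2 is flagged as noteworthy.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Diagnosis, GradeRecord, Modality, GRADES

__all__ = [
    "ConfidenceLevel",
    "ContingencyTable",
    "ChiSquareResult",
    "confidence_level",
    "confidence_crosstab",
    "chi_square_independence",
    "standardized_residuals",
    "bonferroni_adjust",
    "modality_pair_tests",
    "RESIDUAL_FLAG_THRESHOLD",
]

#: |standardized residual| above which a cell is flagged as noteworthy.
RESIDUAL_FLAG_THRESHOLD = 2.0


class ConfidenceLevel(Enum):
    HIGH = "HIGH"
    MEDIUM = "MEDIUM"
    LOW = "LOW"


_LEVEL_OF_GRADE = {
    0: ConfidenceLevel.HIGH,
    5: ConfidenceLevel.HIGH,
    1: ConfidenceLevel.MEDIUM,
    4: ConfidenceLevel.MEDIUM,
    2: ConfidenceLevel.LOW,
    3: ConfidenceLevel.LOW,
}

_LEVEL_ORDER = [ConfidenceLevel.HIGH, ConfidenceLevel.MEDIUM, ConfidenceLevel.LOW]


def confidence_level(grade: int) -> ConfidenceLevel:
    """Fixed partition of grades onto confidence levels: {0,5} high, {1,4} medium, {2,3} low."""
    if grade not in GRADES:
        raise ValueError(f"grade must be in {{0..5}}, got {grade!r}")
    return _LEVEL_OF_GRADE[grade]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of confidence levels (rows) against a second factor (columns)."""

    counts: pd.DataFrame  # index: level labels, columns: factor labels

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("contingency counts must be non-negative integers")

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def row_margins(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def zero_rows(self) -> list[str]:
        return [str(i) for i in self.counts.index[self.row_margins == 0]]


@dataclass(frozen=True)
class ChiSquareResult:
    """Pearson chi-square test of independence with diagnostics.

    ``valid`` is True when every expected count exceeds 5 (the usual adequacy
    check); it is a warning flag, the test is computed regardless.
    ``collapsed_levels`` lists confidence levels dropped because they had zero
    counts across all columns (each dropped row reduces df by the number of
    columns minus one).
    """

    statistic: float
    df: int
    p_value: float
    observed: pd.DataFrame
    expected: pd.DataFrame
    residuals: pd.DataFrame
    valid: bool
    collapsed_levels: tuple[str, ...] = ()

    def noteworthy_cells(self, threshold: float = RESIDUAL_FLAG_THRESHOLD) -> pd.DataFrame:
        """Boolean mask of cells whose |standardized residual| exceeds ``threshold``."""
        return self.residuals.abs() > threshold


def confidence_crosstab(
    records: Iterable[GradeRecord],
    column_factor: str,
    column_levels: Sequence[str] | None = None,
) -> ContingencyTable:
    """3 x k table of confidence-level counts against ``column_factor``.

    ``column_factor`` is one of ``"modality"``, ``"diagnosis"``, ``"grader"``.
    ``column_levels`` restricts and orders the columns (e.g. one modality pair
    for a pairwise comparison); by default every level present is used, in
    first-appearance order. Rows are always HIGH, MEDIUM, LOW; empty rows are
    retained (callers may collapse them in the test stage).
    """
    extractors = {
        "modality": lambda r: r.modality.value,
        "diagnosis": lambda r: r.diagnosis.value,
        "grader": lambda r: r.grader_id,
    }
    if column_factor not in extractors:
        raise ValueError(f"column_factor must be one of {sorted(extractors)}")
    extract = extractors[column_factor]

    records = list(records)
    if column_levels is None:
        seen: dict[str, None] = {}
        for r in records:
            seen.setdefault(extract(r), None)
        column_levels = list(seen)
    else:
        column_levels = list(column_levels)
        records = [r for r in records if extract(r) in set(column_levels)]
    if not column_levels:
        raise ValueError("no column levels present in the records")

    counts = pd.DataFrame(
        0,
        index=[lvl.value for lvl in _LEVEL_ORDER],
        columns=column_levels,
        dtype=int,
    )
    for r in records:
        counts.loc[confidence_level(r.grade).value, extract(r)] += 1
    return ContingencyTable(counts)


def standardized_residuals(observed: pd.DataFrame, expected: pd.DataFrame) -> pd.DataFrame:
    """Pearson standardized residuals (O - E) / sqrt(E), cellwise.

    The squared residuals sum to the chi-square statistic. Raises on zero
    expected counts (a zero margin), which make the residual undefined.
    """
    e = expected.to_numpy(dtype=float)
    if (e <= 0).any():
        raise ValueError("zero expected count: collapse the empty row/column first")
    r = (observed.to_numpy(dtype=float) - e) / np.sqrt(e)
    return pd.DataFrame(r, index=observed.index, columns=observed.columns)


def chi_square_independence(
    table: ContingencyTable, collapse_zero_rows: bool = True
) -> ChiSquareResult:
    """Pearson chi-square test of independence on a confidence contingency table.

    All-zero confidence rows are dropped first when ``collapse_zero_rows`` (the
    default), recording the action in ``collapsed_levels``; with collapsing
    disabled a zero margin is an error. No continuity correction is applied at
    any table size. df = (rows - 1)(cols - 1) after collapsing.
    """
    counts = table.counts
    collapsed: tuple[str, ...] = ()
    zero = table.zero_rows()
    if zero:
        if not collapse_zero_rows:
            raise ValueError(f"zero-count confidence level(s) {zero} and collapsing disabled")
        collapsed = tuple(zero)
        counts = counts.loc[counts.sum(axis=1) > 0]
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("zero column margin: remove empty columns before testing")
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError(
            f"need at least 2 non-degenerate rows and columns, got {counts.shape}"
        )

    chi2, p, df, expected = stats.chi2_contingency(counts.to_numpy(), correction=False)
    expected_df = pd.DataFrame(expected, index=counts.index, columns=counts.columns)
    residuals = standardized_residuals(counts, expected_df)
    return ChiSquareResult(
        statistic=float(chi2),
        df=int(df),
        p_value=float(p),
        observed=counts.copy(),
        expected=expected_df,
        residuals=residuals,
        valid=bool((expected > 5).all()),
        collapsed_levels=collapsed,
    )


def bonferroni_adjust(
    p_values: Sequence[float], alpha: float = 0.05
) -> list[tuple[float, bool]]:
    """Bonferroni correction: adjusted p = min(1, m*p); reject iff raw p <= alpha/m."""
    if len(p_values) == 0:
        raise ValueError("empty p-value list")
    m = len(p_values)
    out = []
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {p}")
        out.append((min(1.0, m * p), p <= alpha / m))
    return out


def modality_pair_tests(
    records: Sequence[GradeRecord],
    alpha: float = 0.05,
    diagnoses: Sequence[Diagnosis] | None = None,
    modalities: Sequence[Modality] | None = None,
) -> pd.DataFrame:
    """All pairwise confidence-vs-modality chi-square tests, per diagnosis.

    For each diagnosis and each unordered modality pair (A, B), tests whether
    the confidence-level mix differs between the two conditions. The Bonferroni
    family is all pairs within one diagnosis. Returns a DataFrame with columns
    diagnosis, factor_A, factor_B, df, chi2, p, significant_after_bonferroni.

    A degenerate pair (a single non-zero confidence level after collapsing,
    i.e. the mix is constant) carries no evidence of association and is listed
    with df 0, statistic 0 and p = 1.
    """
    if diagnoses is None:
        diagnoses = list(Diagnosis)
    if modalities is None:
        modalities = list(Modality)
    rows = []
    for diag in diagnoses:
        subset = [r for r in records if r.diagnosis is diag]
        results = []
        for i, a in enumerate(modalities):
            for b in modalities[i + 1 :]:
                tab = confidence_crosstab(
                    subset, "modality", column_levels=[a.value, b.value]
                )
                try:
                    res = chi_square_independence(tab)
                    stat, df_, p = res.statistic, res.df, res.p_value
                except ValueError:  # one confidence level only: nothing to test
                    stat, df_, p = 0.0, 0, 1.0
                results.append((a.value, b.value, stat, df_, p))
        decisions = bonferroni_adjust([p for *_, p in results], alpha)
        for (a, b, stat, df_, p), (_, reject) in zip(results, decisions):
            rows.append(
                {
                    "diagnosis": diag.value,
                    "factor_A": a,
                    "factor_B": b,
                    "df": df_,
                    "chi2": stat,
                    "p": p,
                    "significant_after_bonferroni": reject,
                }
            )
    return pd.DataFrame(rows)
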
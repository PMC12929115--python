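"""Domain vocabulary and grade-record data model for multi-reader optic disc grading.

A reader study shows each grader a set of optic nerve head images for every eye
under several imaging-modality conditions. The grader assigns a single ordinal
grade on a 0-5 confidence-weighted scale: 0 = definitely no edema, 5 = definitely
edema, intermediate grades encode decreasing certainty toward the middle. Eyes
belong to one of three diagnostic classes: healthy controls and optic disc drusen
(ODD, pseudoedema) have a true grade of 0; optic disc edema (ODE, here NAION) has
a true grade of 5.

This module defines those vocabularies, the atomic :class:`GradeRecord`
observation, the :class:`StudyDesign` metadata, and strict CSV readers/writers
shared by every downstream stage.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Diagnosis",
    "Eye",
    "Modality",
    "GradeRecord",
    "StudyDesign",
    "UnitDefinition",
    "GradeDataError",
    "GRADES",
    "CSV_COLUMNS",
    "read_grades",
    "write_grades",
]

#: The six permissible grades of the confidence-weighted scale.
GRADES: tuple[int, ...] = (0, 1, 2, 3, 4, 5)

#: Mandatory CSV header, in order.
CSV_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "eye",
    "diagnosis",
    "grader_id",
    "modality",
    "grade",
)


class GradeDataError(ValueError):
    """Raised for any malformed grade dataset (bad grade, duplicate key, ...)."""


class Diagnosis(Enum):
    """True diagnostic class of an eye.

    ``true_grade`` is the grade a perfectly confident, perfectly correct grader
    would assign: 0 for classes without true edema (controls and drusen
    pseudoedema), 5 for true optic disc edema.
    """

    CONTROL = "CONTROL"
    ODD = "ODD"
    ODE = "ODE"

    @property
    def true_grade(self) -> int:
        return 5 if self is Diagnosis.ODE else 0


class Eye(Enum):
    OD = "OD"
    OS = "OS"


class Modality(Enum):
    """One of the eight image-set conditions shown to a grader.

    Four single modalities, three duals pairing color fundus photography with
    another modality, and the all-modality condition.
    """

    COLOR = "COLOR"
    FAF = "FAF"
    NIR = "NIR"
    RNFL = "RNFL"
    COLOR_FAF = "COLOR_FAF"
    COLOR_NIR = "COLOR_NIR"
    COLOR_RNFL = "COLOR_RNFL"
    ALL = "ALL"

    @property
    def components(self) -> tuple["Modality", ...]:
        """Constituent single modalities of this condition."""
        return _COMPONENTS[self]

    @property
    def display_name(self) -> str:
        return _DISPLAY_NAMES[self]


_COMPONENTS: dict[Modality, tuple[Modality, ...]] = {
    Modality.COLOR: (Modality.COLOR,),
    Modality.FAF: (Modality.FAF,),
    Modality.NIR: (Modality.NIR,),
    Modality.RNFL: (Modality.RNFL,),
    Modality.COLOR_FAF: (Modality.COLOR, Modality.FAF),
    Modality.COLOR_NIR: (Modality.COLOR, Modality.NIR),
    Modality.COLOR_RNFL: (Modality.COLOR, Modality.RNFL),
    Modality.ALL: (Modality.COLOR, Modality.FAF, Modality.NIR, Modality.RNFL),
}

_DISPLAY_NAMES: dict[Modality, str] = {
    Modality.COLOR: "Color",
    Modality.FAF: "FAF",
    Modality.NIR: "NIR",
    Modality.RNFL: "RNFL",
    Modality.COLOR_FAF: "Color + FAF",
    Modality.COLOR_NIR: "Color + NIR",
    Modality.COLOR_RNFL: "Color + RNFL",
    Modality.ALL: "All modalities",
}


class UnitDefinition(Enum):
    """What counts as one statistical unit in the repeated-measures analysis.

    ``EYE_BY_GRADER`` treats every (subject, eye, grader) triple as an
    independent unit (the default; each eye contributes one within-profile per
    grader). ``SUBJECT_BY_GRADER`` averages fellow eyes of bilateral subjects
    first, so the unit is (subject, grader).
    """

    EYE_BY_GRADER = "eye_by_grader"
    SUBJECT_BY_GRADER = "subject_by_grader"


@dataclass(frozen=True)
class GradeRecord:
    """One grader's 0-5 rating of one eye under one modality condition."""

    subject_id: str
    eye: Eye
    diagnosis: Diagnosis
    grader_id: str
    modality: Modality
    grade: int

    def __post_init__(self) -> None:
        if not isinstance(self.grade, int) or isinstance(self.grade, bool):
            raise GradeDataError(f"grade must be an integer, got {self.grade!r}")
        if self.grade not in GRADES:
            raise GradeDataError(
                f"grade must be in {{0..5}}, got {self.grade} "
                f"(subject {self.subject_id}, eye {self.eye.value})"
            )

    @property
    def key(self) -> tuple[str, str, str, str]:
        """Uniqueness key within a dataset."""
        return (self.subject_id, self.eye.value, self.grader_id, self.modality.value)


@dataclass(frozen=True)
class StudyDesign:
    """Design metadata: which factor levels a dataset may reference."""

    diagnoses: tuple[Diagnosis, ...] = tuple(Diagnosis)
    graders: tuple[str, ...] = ("G1", "G2")
    modalities: tuple[Modality, ...] = tuple(Modality)
    unit_definition: UnitDefinition = UnitDefinition.EYE_BY_GRADER

    def validate_records(self, records: Iterable[GradeRecord]) -> None:
        """Raise if any record references a factor level not in this design."""
        graders = set(self.graders)
        diagnoses = set(self.diagnoses)
        modalities = set(self.modalities)
        for rec in records:
            if rec.diagnosis not in diagnoses:
                raise GradeDataError(f"diagnosis {rec.diagnosis.value} not in design")
            if rec.grader_id not in graders:
                raise GradeDataError(f"grader {rec.grader_id!r} not in design")
            if rec.modality not in modalities:
                raise GradeDataError(f"modality {rec.modality.value} not in design")


def _parse_enum(cls, raw: str, column: str, row_no: int):
    try:
        return cls(raw)
    except ValueError:
        valid = ", ".join(m.value for m in cls)
        raise GradeDataError(
            f"row {row_no}: unknown {column} {raw!r} (expected one of: {valid})"
        ) from None


def _parse_grade(raw: str, row_no: int) -> int:
    text = raw.strip()
    try:
        value = int(text)
    except ValueError:
        raise GradeDataError(f"row {row_no}: grade {raw!r} is not an integer") from None
    # reject floats masquerading as ints ("3.0") and out-of-range values alike
    if text not in {str(g) for g in GRADES}:
        raise GradeDataError(f"row {row_no}: grade {value} outside the 0-5 scale")
    return value


def read_grades(path: str | Path, design: StudyDesign | None = None) -> list[GradeRecord]:
    """Read a long-format grade CSV into validated :class:`GradeRecord` objects.

    Validation is total: every malformed row (missing column, grade outside
    0-5, duplicate (subject, eye, grader, modality) key, unknown factor label)
    raises :class:`GradeDataError` naming the offending row; nothing is
    silently dropped.
    """
    path = Path(path)
    records: list[GradeRecord] = []
    seen: set[tuple[str, str, str, str]] = set()
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise GradeDataError(f"{path}: empty file, expected header {CSV_COLUMNS}")
        missing = set(CSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise GradeDataError(f"{path}: missing column(s) {sorted(missing)}")
        for row_no, row in enumerate(reader, start=2):  # header is line 1
            if any(row.get(col) is None for col in CSV_COLUMNS):
                raise GradeDataError(f"row {row_no}: short row, expected {len(CSV_COLUMNS)} fields")
            rec = GradeRecord(
                subject_id=row["subject_id"].strip(),
                eye=_parse_enum(Eye, row["eye"].strip(), "eye", row_no),
                diagnosis=_parse_enum(Diagnosis, row["diagnosis"].strip(), "diagnosis", row_no),
                grader_id=row["grader_id"].strip(),
                modality=_parse_enum(Modality, row["modality"].strip(), "modality", row_no),
                grade=_parse_grade(row["grade"], row_no),
            )
            if rec.key in seen:
                raise GradeDataError(f"row {row_no}: duplicate record key {rec.key}")
            seen.add(rec.key)
            records.append(rec)
    if design is not None:
        design.validate_records(records)
    return records


def write_grades(records: Sequence[GradeRecord], path: str | Path) -> None:
    """Write records to CSV in the canonical schema (re-readable round trip)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(CSV_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.subject_id,
                    rec.eye.value,
                    rec.diagnosis.value,
                    rec.grader_id,
                    rec.modality.value,
                    rec.grade,
                ]
            )
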
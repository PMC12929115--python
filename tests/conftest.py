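import numpy as np
import pandas as pd
import pytest

from onhreader import (
    Diagnosis,
    Eye,
    GradeRecord,
    Modality,
    generate_cohort,
    preset_study_like,
)


def make_record(
    subject="S001",
    eye=Eye.OD,
    diagnosis=Diagnosis.ODE,
    grader="G1",
    modality=Modality.COLOR,
    grade=5,
):
    return GradeRecord(
        subject_id=subject,
        eye=eye,
        diagnosis=diagnosis,
        grader_id=grader,
        modality=modality,
        grade=grade,
    )


@pytest.fixture(scope="session")
def preset_records():
    """One simulated study-shaped cohort (149 eyes x 2 graders x 8 modalities)."""
    return generate_cohort(preset_study_like(seed=11))


@pytest.fixture()
def perfect_records():
    """Every grader assigns the true grade to every eye: a 2-eye-per-diagnosis toy."""
    records = []
    for diag in Diagnosis:
        for i in range(2):
            for grader in ("G1", "G2"):
                for modality in Modality:
                    records.append(
                        make_record(
                            subject=f"{diag.value}-{i}",
                            diagnosis=diag,
                            grader=grader,
                            modality=modality,
                            grade=diag.true_grade,
                        )
                    )
    return records


def balanced_splitplot(a=2, b=2, k=2, n=4, seed=0, effects=None):
    """Balanced a x b x k split-plot long DataFrame with n units per cell.

    ``effects`` maps term names ('A', 'B', 'W', 'AW', ...) to scalar magnitudes
    used to build deterministic level offsets; unset terms are zero.
    """
    eff = {"A": 0.0, "B": 0.0, "W": 0.0, "AW": 0.0, "BW": 0.0, "ABW": 0.0}
    if effects:
        eff.update(effects)
    rng = np.random.default_rng(seed)
    rows = []
    for ia in range(a):
        for ib in range(b):
            for unit in range(n):
                uid = f"u{ia}{ib}{unit}"
                base = rng.normal(0, 1.0)
                for iw in range(k):
                    mean = (
                        eff["A"] * (ia - (a - 1) / 2)
                        + eff["B"] * (ib - (b - 1) / 2)
                        + eff["W"] * (iw - (k - 1) / 2)
                        + eff["AW"] * (ia - (a - 1) / 2) * (iw - (k - 1) / 2)
                    )
                    rows.append(
                        dict(
                            unit=uid,
                            A=f"a{ia}",
                            B=f"b{ib}",
                            W=f"w{iw}",
                            y=mean + base + rng.normal(0, 1.0),
                        )
                    )
    return pd.DataFrame(rows)
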
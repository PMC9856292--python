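"""The packaged patient cohort table.

Twenty-one prolonged disorders-of-consciousness patients who received a
course of HD-tDCS, with demographics, etiology, days since onset, and
CRS-R total scores at baseline (T0), after one session (T1) and after the
full course (T2). Patients whose total CRS-R improved from T0 to T2 form
the responsive (RE) group; the rest the non-responsive (N-RE) group.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

CRSR_MIN, CRSR_MAX = 0, 23


def cohort_fixture() -> pd.DataFrame:
    """Load the 21-patient cohort table (12 RE, 9 N-RE).

    Columns: patient_id, group, sex, age, etiology, course_days,
    crsr_t0/t1/t2, diagnosis_t0/t1/t2, followup_3mo.
    """
    with resources.files("msdoc.data").joinpath("cohort_table.csv").open() as fh:
        table = pd.read_csv(fh)
    validate_cohort(table)
    return table


def validate_cohort(table: pd.DataFrame) -> None:
    """Check CRS-R bounds and group-definition consistency."""
    for col in ("crsr_t0", "crsr_t1", "crsr_t2"):
        scores = table[col]
        if ((scores < CRSR_MIN) | (scores > CRSR_MAX)).any():
            raise ValueError(f"{col} outside the 0-23 CRS-R range")
    expected = classify_responders(table)
    if not (expected == table["group"]).all():
        bad = table.loc[expected != table["group"], "patient_id"].tolist()
        raise ValueError(f"group label inconsistent with CRS-R change for {bad}")


def classify_responders(table: pd.DataFrame) -> pd.Series:
    """RE iff the T2 total CRS-R exceeds the T0 total, else N-RE."""
    for col in ("crsr_t0", "crsr_t2"):
        if col not in table or table[col].isna().any():
            raise ValueError(f"missing CRS-R scores in {col}")
    return pd.Series(
        ["RE" if t2 > t0 else "N-RE" for t0, t2 in zip(table["crsr_t0"], table["crsr_t2"])],
        index=table.index,
        name="group",
    )
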
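"""Cohort domain types shared by the simulator and the statistics layer.

The study design has four groups — controls, pure AD-related cognitive
impairment (ADCI), pure Lewy-body-related cognitive impairment (LBCI),
and mixed disease — coded downstream as two binary disease flags (the
mixed group has both). Six covariates enter every model: age, sex,
education, deep and periventricular white-matter hyperintensity grades
(ordinal 1-3, entered numerically), and intracranial volume. Cognition
is a battery of 14 standardized (z-scored) neuropsychological tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "GROUPS",
    "COVARIATES",
    "COGNITION_TESTS",
    "CohortRecord",
    "records_to_frame",
    "validate_cohort_frame",
]

GROUPS = ("control", "pure_adci", "pure_lbci", "mixed")

COVARIATES = ("age", "sex", "education", "dwmh", "pwmh", "icv")

COGNITION_TESTS = (
    "digit_span_backward",
    "k_bnt",
    "rcft_copy",
    "svlt_immediate_recall",
    "svlt_delayed_recall",
    "svlt_recognition",
    "rcft_immediate_recall",
    "rcft_delayed_recall",
    "rcft_recognition",
    "cowat_animal",
    "cowat_supermarket",
    "cowat_phonemic",
    "stroop_color_reading",
    "k_mmse",
)

_ADCI_GROUPS = {"pure_adci", "mixed"}
_LBCI_GROUPS = {"pure_lbci", "mixed"}


@dataclass
class CohortRecord:
    """One subject's metadata, disease flags, covariates and cognition."""

    subject_id: str
    group: str
    age: float
    sex: int
    education: float
    dwmh: int
    pwmh: int
    icv: float
    cognition: dict[str, float]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if set(self.cognition) != set(COGNITION_TESTS):
            raise ValueError("cognition must contain exactly the 14 battery scores")
        if self.dwmh not in (1, 2, 3) or self.pwmh not in (1, 2, 3):
            raise ValueError("WMH grades must be ordinal 1-3")

    @property
    def adci(self) -> int:
        return int(self.group in _ADCI_GROUPS)

    @property
    def lbci(self) -> int:
        return int(self.group in _LBCI_GROUPS)


def records_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    """One row per subject: id, group, flags, covariates, 14 scores."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "group": r.group,
            "adci": r.adci,
            "lbci": r.lbci,
            "age": r.age,
            "sex": r.sex,
            "education": r.education,
            "dwmh": r.dwmh,
            "pwmh": r.pwmh,
            "icv": r.icv,
        }
        row.update({t: r.cognition[t] for t in COGNITION_TESTS})
        rows.append(row)
    return pd.DataFrame(rows)


def validate_cohort_frame(df: pd.DataFrame, require_cognition: bool = True) -> None:
    """Check the cohort table for the columns and codings the models need."""
    needed = ["subject_id", "group", "adci", "lbci", *COVARIATES]
    if require_cognition:
        needed += list(COGNITION_TESTS)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    bad = df.loc[~df["group"].isin(GROUPS), "group"].unique()
    if len(bad):
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    expect_adci = df["group"].isin(_ADCI_GROUPS).astype(int)
    expect_lbci = df["group"].isin(_LBCI_GROUPS).astype(int)
    if not (df["adci"].astype(int) == expect_adci).all() or not (
        df["lbci"].astype(int) == expect_lbci
    ).all():
        raise ValueError("adci/lbci flags inconsistent with group labels")
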
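"""Cohort assembly: exclusion filters and per-patient outcome summaries.

All downstream analysis is at the level of the patient, not the
patient-day: each patient contributes the maximum and the minimum of their
daily priority score, priority group, SOFA score, and SOFA points across
all retained patient-days.  The maximum reflects the day a patient would
most likely be denied a scarce resource; the minimum the day they would
most likely receive one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExclusionLog", "apply_exclusions", "summarize_patients", "OUTCOMES"]

#: the eight per-patient outcomes (extremum, daily quantity)
OUTCOMES = [
    f"{ext}_{var}"
    for var in ("priority_score", "priority_group", "sofa_score", "sofa_points")
    for ext in ("max", "min")
]


@dataclass
class ExclusionLog:
    """Counts of records removed by each exclusion rule."""

    days_missing_sofa: int = 0
    patients_missing_comorbidity: int = 0
    days_of_excluded_patients: int = 0
    notes: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "patient_days_missing_sofa": self.days_missing_sofa,
            "patients_missing_comorbidity_data": self.patients_missing_comorbidity,
            "patient_days_of_excluded_patients": self.days_of_excluded_patients,
        }


def _comorbidity_known(series: pd.Series) -> pd.Series:
    return series.notna() & (series.astype(str) != "") & (series.astype(str) != "nan")


def apply_exclusions(
    patient_days: pd.DataFrame, patients: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, ExclusionLog]:
    """Drop patient-days without a SOFA score and patients without
    comorbidity data; every removal is counted in the returned log.

    Raises on a patient-day whose ``patient_id`` has no patient record.
    """
    log = ExclusionLog()

    orphans = set(patient_days["patient_id"]) - set(patients["patient_id"])
    if orphans:
        raise ValueError(
            f"patient-day rows reference unknown patients: {sorted(orphans)[:5]}"
        )

    has_sofa = patient_days["sofa_score"].notna()
    log.days_missing_sofa = int((~has_sofa).sum())
    days = patient_days[has_sofa]

    known = _comorbidity_known(patients["comorbidities"])
    log.patients_missing_comorbidity = int((~known).sum())
    kept_patients = patients[known]
    before = len(days)
    days = days[days["patient_id"].isin(set(kept_patients["patient_id"]))]
    log.days_of_excluded_patients = before - len(days)

    # patients whose every day was excluded contribute no outcomes
    kept_patients = kept_patients[
        kept_patients["patient_id"].isin(set(days["patient_id"]))
    ]
    return days.reset_index(drop=True), kept_patients.reset_index(drop=True), log


def summarize_patients(scored_days: pd.DataFrame) -> pd.DataFrame:
    """Componentwise max/min of the four daily quantities per patient.

    ``scored_days`` must carry ``patient_id``, ``priority_score``,
    ``priority_group``, ``sofa_score`` and ``sofa_points`` (the output of
    :func:`csctriage.scoring.score_table` after exclusions).  Raises if a
    patient has zero retained days (empty input yields an empty frame).
    """
    required = [
        "patient_id",
        "priority_score",
        "priority_group",
        "sofa_score",
        "sofa_points",
    ]
    missing = [c for c in required if c not in scored_days.columns]
    if missing:
        raise ValueError(f"scored_days missing columns: {missing}")
    if scored_days[required[1:]].isna().any().any():
        raise ValueError(
            "scored_days contains unscored rows; run apply_exclusions first"
        )
    if len(scored_days) == 0:
        return pd.DataFrame(
            columns=["patient_id", "n_days", *OUTCOMES]
        ).astype({"n_days": int})

    g = scored_days.groupby("patient_id")
    out = pd.DataFrame({"n_days": g.size()})
    for var in ("priority_score", "priority_group", "sofa_score", "sofa_points"):
        out[f"max_{var}"] = g[var].max().astype(int)
        out[f"min_{var}"] = g[var].min().astype(int)
    return out.reset_index()
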
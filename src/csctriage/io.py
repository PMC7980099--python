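"""Cohort table IO, validation, configuration and report writing.

Conventions
-----------
* Tables are plain CSV.  Missing values are empty fields; on read they are
  surfaced as the uniform ``"Unknown"`` level for categorical covariates
  (an empty ``comorbidities`` field means comorbidity data unavailable,
  the string ``"none"`` means assessed-and-absent).
* Dates are ISO-8601; ``(patient_id, date)`` must be unique and every
  patient-day must reference a patient row.
* Config and truth files are YAML.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .scoring import DEFAULT_GROUP_MAP, SOFA_POINT_CUTS, ComorbidityCatalog

__all__ = [
    "PATIENT_COLUMNS",
    "PATIENT_DAY_COLUMNS",
    "CohortBundle",
    "TriageConfig",
    "read_cohort",
    "write_cohort",
    "write_report",
    "format_irr",
    "format_p",
    "log_run",
]

logger = logging.getLogger("csctriage")

#: column dictionary, patients table
PATIENT_COLUMNS = {
    "patient_id": "unique patient identifier",
    "age_years": "age in years (continuous; empty = unknown)",
    "sex": "Male | Female | (empty = unknown)",
    "race": "White | Black | Asian | Multiracial | (empty = unknown)",
    "ethnicity": "Non-Hispanic | Hispanic | (empty = unknown)",
    "language": "English | Spanish | Other | (empty = unknown)",
    "income_band": "<25k | 25-<50k | 50-<75k | >=75k | (empty = unknown)",
    "insurer": "Medicare/Medicaid | Commercial | None | (empty = unknown)",
    "hospital": "tertiary | quaternary",
    "covid_unit": "True if admitted to a COVID-19 unit",
    "comorbidities": "semicolon-joined catalog codes; 'none' = assessed, none found; empty = data unavailable",
    "short_term_recovery_comorbidity": "tiebreak flag (optional; default False)",
    "essential_function": "tiebreak flag (optional; default False)",
}
_PATIENT_REQUIRED = [
    "patient_id", "age_years", "sex", "race", "ethnicity", "language",
    "income_band", "insurer", "hospital", "covid_unit", "comorbidities",
]

#: column dictionary, patient-day table
PATIENT_DAY_COLUMNS = {
    "patient_id": "foreign key into the patients table",
    "date": "ISO-8601 calendar date",
    "sofa_score": "daily SOFA total 0-24 (empty = not available that day)",
}
_DAY_REQUIRED = ["patient_id", "date", "sofa_score"]

_CATEGORICALS = ["sex", "race", "ethnicity", "language", "income_band", "insurer"]


@dataclass
class TriageConfig:
    """Run configuration: SOFA bands, score->group map, catalog, tiebreaks."""

    sofa_point_cuts: tuple = SOFA_POINT_CUTS
    group_map: Mapping[int, tuple] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_MAP)
    )
    catalog: ComorbidityCatalog = field(default_factory=ComorbidityCatalog.default)
    tiebreak_enabled: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "TriageConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = {}
        if "sofa_point_cuts" in raw:
            kw["sofa_point_cuts"] = tuple(raw["sofa_point_cuts"])
        if "group_map" in raw:
            kw["group_map"] = {
                int(g): tuple(rng) for g, rng in raw["group_map"].items()
            }
        if "comorbidity_catalog" in raw:
            kw["catalog"] = ComorbidityCatalog.from_dict(raw["comorbidity_catalog"])
        if "tiebreak_enabled" in raw:
            kw["tiebreak_enabled"] = bool(raw["tiebreak_enabled"])
        return cls(**kw)


@dataclass
class CohortBundle:
    """A validated cohort: the two tables plus catalog, config, provenance."""

    patients: pd.DataFrame
    patient_days: pd.DataFrame
    catalog: ComorbidityCatalog
    config: TriageConfig
    provenance: dict = field(default_factory=dict)


def _read_csv(path) -> pd.DataFrame:
    # keep literal "None" (the insurer level); only empty fields are missing
    return pd.read_csv(path, keep_default_na=False, na_values=[""])


def read_cohort(
    patients_path,
    patient_days_path,
    config: Optional[TriageConfig] = None,
    provenance: Optional[dict] = None,
) -> CohortBundle:
    """Read, type and validate the two cohort tables into a bundle.

    Raises ``ValueError`` naming the offending row/column on schema
    violations, duplicate patient-days, or broken referential integrity.
    """
    config = config or TriageConfig()
    patients = _read_csv(patients_path)
    days = _read_csv(patient_days_path)

    for name, df, req in (
        ("patients", patients, _PATIENT_REQUIRED),
        ("patient_days", days, _DAY_REQUIRED),
    ):
        missing = [c for c in req if c not in df.columns]
        if missing:
            raise ValueError(f"{name} table missing columns: {missing}")

    dup = patients["patient_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate patient_id: {patients.loc[dup, 'patient_id'].tolist()[:5]}"
        )
    dupday = days.duplicated(subset=["patient_id", "date"])
    if dupday.any():
        keys = days.loc[dupday, ["patient_id", "date"]].itertuples(index=False)
        raise ValueError(f"duplicate patient-day rows: {[tuple(k) for k in keys][:5]}")
    orphans = set(days["patient_id"]) - set(patients["patient_id"])
    if orphans:
        raise ValueError(
            f"patient_days reference unknown patients: {sorted(orphans)[:5]}"
        )

    patients = patients.copy()
    for col in _CATEGORICALS:
        patients[col] = patients[col].fillna("Unknown").replace(
            {"unknown": "Unknown"}
        )
    patients["age_years"] = pd.to_numeric(patients["age_years"], errors="raise")
    patients["covid_unit"] = patients["covid_unit"].astype(bool)
    for col in ("short_term_recovery_comorbidity", "essential_function"):
        if col in patients.columns:
            patients[col] = patients[col].fillna(False).astype(bool)
        else:
            patients[col] = False

    days = days.copy()
    days["sofa_score"] = pd.to_numeric(days["sofa_score"], errors="raise")
    bad = days["sofa_score"].dropna()
    if len(bad) and ((bad < 0) | (bad > 24)).any():
        row = days.index[days["sofa_score"].notna() & ((days["sofa_score"] < 0) | (days["sofa_score"] > 24))][0]
        raise ValueError(f"sofa_score out of [0, 24] at patient_days row {row}")

    known = config.catalog
    for i, v in patients["comorbidities"].items():
        if pd.isna(v) or v in ("", "none"):
            continue
        for code in str(v).split(";"):
            if code not in known:
                raise ValueError(
                    f"unknown comorbidity code {code!r} at patients row {i}"
                )

    return CohortBundle(
        patients=patients,
        patient_days=days,
        catalog=config.catalog,
        config=config,
        provenance=provenance or {"source": str(patients_path)},
    )


def write_cohort(patients: pd.DataFrame, patient_days: pd.DataFrame, outdir) -> dict:
    """Write the two cohort tables to ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ppath = outdir / "patients.csv"
    dpath = outdir / "patient_days.csv"
    patients.to_csv(ppath, index=False)
    patient_days.to_csv(dpath, index=False)
    return {"patients": str(ppath), "patient_days": str(dpath)}


def format_irr(irr: float, lo: float, hi: float) -> str:
    """Journal-style point estimate with CI: ``1.00 (0.89-1.12)``."""
    return f"{irr:.2f} ({lo:.2f}-{hi:.2f})"


def format_p(p: float) -> str:
    """Journal-style p-value: ``<.001``, ``.003``, ``.05``, ``.94``."""
    if np.isnan(p):
        return "NA"
    if p < 0.001:
        return "<.001"
    if p > 0.99:
        return ">.99"
    digits = 3 if p < 0.01 else 2
    return f"{p:.{digits}f}".lstrip("0")


def write_report(results, outdir) -> dict:
    """Write a fitted :class:`~csctriage.audit.DisparityAuditResults` as a
    deterministic file set: descriptive tests, stacked IRR tables (primary
    + both sensitivity families), reprioritization fractions, the
    exclusion log, and a human-readable report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _stack(tables) -> pd.DataFrame:
        if not tables:
            return pd.DataFrame()
        return pd.concat(tables.values(), ignore_index=True)

    def _csv(name: str, df: pd.DataFrame) -> None:
        p = outdir / name
        df.to_csv(p, index=False, float_format="%.6g")
        paths[name] = str(p)

    if results.descriptives:
        _csv(
            "descriptives.csv",
            pd.concat(
                [t.assign(grouping=w) for w, t in results.descriptives.items()],
                ignore_index=True,
            ),
        )
    _csv("irr_primary.csv", _stack(results.irr))
    if results.irr_unknown_sensitivity:
        _csv("irr_unknown_sensitivity.csv", _stack(results.irr_unknown_sensitivity))
    if results.irr_no_ses_sensitivity:
        _csv("irr_no_ses_sensitivity.csv", _stack(results.irr_no_ses_sensitivity))
    _csv(
        "reprioritization.csv",
        pd.concat(
            [t.assign(which=w) for w, t in results.reprioritization.items()],
            ignore_index=True,
        ),
    )
    _csv(
        "exclusions.csv",
        pd.DataFrame([results.model.exclusion_log.as_dict()]),
    )
    rpath = outdir / "report.txt"
    rpath.write_text(results.summary())
    paths["report.txt"] = str(rpath)
    return paths


def log_run(command: str, seed: Optional[int], config: Optional[dict], out=None) -> str:
    """Append a structured one-line run record (command, seed, config hash)."""
    blob = json.dumps(config or {}, sort_keys=True, default=str)
    entry = json.dumps(
        {
            "ts": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "command": command,
            "seed": seed,
            "config_sha1": hashlib.sha1(blob.encode()).hexdigest()[:12],
        }
    )
    logger.info(entry)
    if out is not None:
        path = Path(out) / "csctriage.log"
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "a") as fh:
            fh.write(entry + "\n")
    return entry
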
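"""Daily SOFA (Sequential Organ Failure Assessment) scoring.

The SOFA score grades dysfunction in six organ systems (respiration,
coagulation, liver, cardiovascular, central nervous system, renal) on an
integer 0-4 scale and sums them to a 0-24 total.  It is the short-term
mortality proxy that drives the triage priority score in
:mod:`csctriage.scoring`.

Cut-points live in an editable YAML table (``data/sofa_cutpoints.yaml``)
rather than in code, so SOFA dialects can be swapped without touching the
scoring logic.  Missing components score 0 and are counted in
``SofaResult.n_missing_components`` so callers can filter incomplete days.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import yaml

__all__ = [
    "OrganSystem",
    "VasopressorDose",
    "SofaInputs",
    "SofaResult",
    "load_cutpoints",
    "compute_subscore",
    "compute_sofa",
]


class OrganSystem(str, enum.Enum):
    RESPIRATION = "respiration"
    COAGULATION = "coagulation"
    LIVER = "liver"
    CARDIOVASCULAR = "cardiovascular"
    CNS = "cns"
    RENAL = "renal"


class VasopressorDose(str, enum.Enum):
    """Vasopressor support category, ordered by severity.

    Categories follow the published SOFA cardiovascular row: dobutamine at
    any dose or dopamine <=5 ug/kg/min scores 2; dopamine >5 or
    epinephrine/norepinephrine <=0.1 scores 3; dopamine >15 or
    epinephrine/norepinephrine >0.1 scores 4.
    """

    NONE = "none"
    DOPAMINE_LE5_OR_DOBUTAMINE = "dopamine_le5_or_dobutamine"
    DOPAMINE_GT5_OR_EPI_LE01_OR_NOREPI_LE01 = "dopamine_gt5_or_epi_le01_or_norepi_le01"
    DOPAMINE_GT15_OR_EPI_GT01_OR_NOREPI_GT01 = "dopamine_gt15_or_epi_gt01_or_norepi_gt01"


@dataclass(frozen=True)
class SofaInputs:
    """Physiologic inputs for one patient-day; any field may be absent."""

    pao2_fio2_ratio: Optional[float] = None
    on_respiratory_support: bool = False
    platelets: Optional[float] = None  # 10^3/uL
    bilirubin: Optional[float] = None  # mg/dL
    map_mmHg: Optional[float] = None
    vasopressor: Optional[VasopressorDose] = None
    gcs: Optional[float] = None  # 3-15
    creatinine: Optional[float] = None  # mg/dL
    urine_output_mL_day: Optional[float] = None

    def __post_init__(self) -> None:
        if self.gcs is not None and not (3 <= self.gcs <= 15):
            raise ValueError(f"GCS must be in [3, 15], got {self.gcs}")
        for name in (
            "pao2_fio2_ratio",
            "platelets",
            "bilirubin",
            "map_mmHg",
            "creatinine",
            "urine_output_mL_day",
        ):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.vasopressor is not None and not isinstance(
            self.vasopressor, VasopressorDose
        ):
            object.__setattr__(
                self, "vasopressor", VasopressorDose(self.vasopressor)
            )


@dataclass(frozen=True)
class SofaResult:
    subscores: dict  # OrganSystem -> int 0-4
    total: int  # 0-24
    n_missing_components: int  # 0-6


_CUTPOINTS_CACHE: Optional[dict] = None


def load_cutpoints(path: Optional[str] = None) -> dict:
    """Load the SOFA cut-point table (packaged default, or a user file)."""
    global _CUTPOINTS_CACHE
    if path is None:
        if _CUTPOINTS_CACHE is None:
            text = (
                resources.files("csctriage") / "data" / "sofa_cutpoints.yaml"
            ).read_text()
            _CUTPOINTS_CACHE = yaml.safe_load(text)
        return _CUTPOINTS_CACHE
    with open(path) as fh:
        return yaml.safe_load(fh)


def _band_upper_exclusive(value: float, thresholds: dict) -> int:
    # thresholds: subscore -> upper bound; worse (higher) subscore wins
    score = 0
    for sub in sorted(thresholds):
        if value < thresholds[sub]:
            score = sub
    return score


def _band_upper_inclusive(value: float, thresholds: dict) -> int:
    score = 0
    for sub in sorted(thresholds):
        if value <= thresholds[sub]:
            score = sub
    return score


def _band_lower_inclusive(value: float, thresholds: dict) -> int:
    score = 0
    for sub in sorted(thresholds):
        if value >= thresholds[sub]:
            score = sub
    return score


def compute_subscore(
    system: OrganSystem, inputs: SofaInputs, cutpoints: Optional[dict] = None
) -> int:
    """SOFA subscore (0-4) for one organ system.

    A system whose inputs are all absent scores 0 (missingness is surfaced
    by :func:`compute_sofa`, not imputed as worst-case).
    """
    system = OrganSystem(system)
    cp = (cutpoints or load_cutpoints())[system.value]

    if system is OrganSystem.RESPIRATION:
        if inputs.pao2_fio2_ratio is None:
            return 0
        score = _band_upper_inclusive(
            inputs.pao2_fio2_ratio, cp["pao2_fio2_upper_inclusive"]
        )
        # ventilatory support is part of the definition of subscores 3-4
        if not inputs.on_respiratory_support:
            score = min(score, cp["support_required_from"] - 1)
        return score

    if system is OrganSystem.COAGULATION:
        if inputs.platelets is None:
            return 0
        return _band_upper_inclusive(inputs.platelets, cp["platelets_upper_inclusive"])

    if system is OrganSystem.LIVER:
        if inputs.bilirubin is None:
            return 0
        return _band_lower_inclusive(inputs.bilirubin, cp["bilirubin_lower_inclusive"])

    if system is OrganSystem.CARDIOVASCULAR:
        vp = inputs.vasopressor
        if vp is not None and vp is not VasopressorDose.NONE:
            return cp["vasopressor_scores"][VasopressorDose(vp).value]
        if inputs.map_mmHg is None:
            return 0
        return 1 if inputs.map_mmHg < cp["map_upper_exclusive"] else 0

    if system is OrganSystem.CNS:
        if inputs.gcs is None:
            return 0
        return _band_upper_exclusive(inputs.gcs, {
            sub: ub + 1 for sub, ub in cp["gcs_upper_inclusive"].items()
        })

    if system is OrganSystem.RENAL:
        scores = [0]
        if inputs.creatinine is not None:
            scores.append(
                _band_lower_inclusive(inputs.creatinine, cp["creatinine_lower_inclusive"])
            )
        if inputs.urine_output_mL_day is not None:
            scores.append(
                _band_upper_exclusive(inputs.urine_output_mL_day, cp["urine_upper_exclusive"])
            )
        # worse of creatinine- and urine-based values
        return max(scores)

    raise ValueError(f"unknown organ system: {system!r}")


_SYSTEM_FIELDS = {
    OrganSystem.RESPIRATION: ("pao2_fio2_ratio",),
    OrganSystem.COAGULATION: ("platelets",),
    OrganSystem.LIVER: ("bilirubin",),
    OrganSystem.CARDIOVASCULAR: ("map_mmHg", "vasopressor"),
    OrganSystem.CNS: ("gcs",),
    OrganSystem.RENAL: ("creatinine", "urine_output_mL_day"),
}


def compute_sofa(inputs: SofaInputs, cutpoints: Optional[dict] = None) -> SofaResult:
    """Total SOFA score with per-system subscores and a missingness count."""
    subscores = {}
    n_missing = 0
    for system, fields in _SYSTEM_FIELDS.items():
        if all(getattr(inputs, f) is None for f in fields):
            n_missing += 1
        subscores[system] = compute_subscore(system, inputs, cutpoints)
    return SofaResult(
        subscores=subscores,
        total=sum(subscores.values()),
        n_missing_components=n_missing,
    )
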
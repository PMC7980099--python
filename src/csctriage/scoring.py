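"""Crisis-standards-of-care triage priority scoring and allocation.

The allocation algorithm converts each patient-day into a priority score:

* **SOFA points** (1-4) band the daily SOFA score: <6 -> 1, 6-8 -> 2,
  9-11 -> 3, >=12 -> 4 (short-term mortality).
* **Comorbidity points** (0/2/4) reflect longer-term mortality: 4 if any
  comorbidity expected to reduce 1-year survival is present, else 2 if any
  5-year-survival-reducing comorbidity, else 0.  A patient receives a
  single allotment — points are never summed across comorbidities.
* **Priority score** = SOFA points + comorbidity points, 1 (highest
  priority) through 8 (lowest).
* **Priority group** consolidates scores into 3 groups (default 1-3 -> 1,
  4-5 -> 2, 6-8 -> 3; configurable) used for allocation, with ties broken
  by a fixed cascade ending in a lottery.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "Tier",
    "ComorbidityCatalog",
    "TriageResult",
    "TiebreakProfile",
    "Ordering",
    "SOFA_POINT_CUTS",
    "DEFAULT_GROUP_MAP",
    "sofa_points",
    "comorbidity_points",
    "priority_score",
    "priority_group",
    "sofa_only_group",
    "tiebreak_compare",
    "allocate",
    "score_table",
]

#: upper-exclusive SOFA-score cut-points for points 2, 3, 4
SOFA_POINT_CUTS = (6, 9, 12)

#: priority score range covered by each priority group (inclusive)
DEFAULT_GROUP_MAP = {1: (1, 3), 2: (4, 5), 3: (6, 8)}


class Tier(str, enum.Enum):
    FIVE_YEAR = "five_year"  # 2 points
    ONE_YEAR = "one_year"  # 4 points


@dataclass(frozen=True)
class ComorbidityCatalog:
    """Mapping from comorbidity code to survival-impact tier.

    The default catalog holds the institutional policy's condition lists:
    6 conditions expected to reduce 5-year survival and 9 expected to
    reduce 1-year survival.
    """

    tiers: Mapping[str, Tier]
    labels: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "ComorbidityCatalog":
        text = (
            resources.files("csctriage") / "data" / "comorbidities.yaml"
        ).read_text()
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_dict(cls, spec: Mapping) -> "ComorbidityCatalog":
        tiers, labels = {}, {}
        for tier_name, codes in spec.items():
            tier = Tier(tier_name)
            for code, label in codes.items():
                if code in tiers:
                    raise ValueError(f"comorbidity code {code!r} listed twice")
                tiers[code] = tier
                labels[code] = label
        return cls(tiers=tiers, labels=labels)

    @classmethod
    def from_yaml(cls, path: str) -> "ComorbidityCatalog":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def tier_of(self, code: str) -> Tier:
        try:
            return self.tiers[code]
        except KeyError:
            raise KeyError(f"unknown comorbidity code: {code!r}") from None

    def __contains__(self, code: str) -> bool:
        return code in self.tiers


@dataclass(frozen=True)
class TriageResult:
    sofa_points: int  # 1-4
    comorbidity_points: int  # 0, 2 or 4
    priority_score: int  # 1-8
    priority_group: int  # 1-3


@dataclass(frozen=True)
class TiebreakProfile:
    """Patient attributes consumed by the tiebreak cascade."""

    short_term_recovery_comorbidity: bool = False
    age_years: float = 0.0
    essential_function: bool = False

    def __post_init__(self) -> None:
        if self.age_years < 0:
            raise ValueError("age_years must be non-negative")


class Ordering(str, enum.Enum):
    A_FIRST = "a_first"
    B_FIRST = "b_first"
    TIE = "tie"


def sofa_points(sofa_score: int) -> int:
    """Band a daily SOFA score (0-24) into 1-4 triage points."""
    if not 0 <= sofa_score <= 24:
        raise ValueError(f"SOFA score must be in [0, 24], got {sofa_score}")
    return 1 + int(np.searchsorted(SOFA_POINT_CUTS, sofa_score, side="right"))


def comorbidity_points(
    codes: Iterable[str], catalog: Optional[ComorbidityCatalog] = None
) -> int:
    """Single-allotment comorbidity points: 4 for any 1-year-tier condition,
    else 2 for any 5-year-tier condition, else 0."""
    catalog = catalog or ComorbidityCatalog.default()
    tiers = {catalog.tier_of(c) for c in codes}
    if Tier.ONE_YEAR in tiers:
        return 4
    if Tier.FIVE_YEAR in tiers:
        return 2
    return 0


def priority_score(sofa_pts: int, comorbidity_pts: int) -> int:
    if sofa_pts not in (1, 2, 3, 4):
        raise ValueError(f"sofa_points must be 1-4, got {sofa_pts}")
    if comorbidity_pts not in (0, 2, 4):
        raise ValueError(f"comorbidity_points must be 0, 2 or 4, got {comorbidity_pts}")
    return sofa_pts + comorbidity_pts


def priority_group(
    score: int, group_map: Optional[Mapping[int, tuple]] = None
) -> int:
    """Consolidate a priority score 1-8 into priority group 1-3."""
    if not 1 <= score <= 8:
        raise ValueError(f"priority score must be in [1, 8], got {score}")
    group_map = group_map or DEFAULT_GROUP_MAP
    for group, (lo, hi) in group_map.items():
        if lo <= score <= hi:
            return group
    raise ValueError(f"group map does not cover score {score}")


def sofa_only_group(sofa_pts: int) -> int:
    """Three-group consolidation of SOFA points alone (points 3 and 4 share
    group 3); the comparator for the reprioritization analysis."""
    if sofa_pts not in (1, 2, 3, 4):
        raise ValueError(f"sofa_points must be 1-4, got {sofa_pts}")
    return min(sofa_pts, 3)


def triage(
    sofa_score: int,
    codes: Iterable[str] = (),
    catalog: Optional[ComorbidityCatalog] = None,
    group_map: Optional[Mapping[int, tuple]] = None,
) -> TriageResult:
    """Full per-patient-day triage: SOFA score + comorbidities -> TriageResult."""
    sp = sofa_points(sofa_score)
    cp = comorbidity_points(codes, catalog)
    score = priority_score(sp, cp)
    return TriageResult(sp, cp, score, priority_group(score, group_map))


def _tiebreak_key(result: TriageResult, profile: TiebreakProfile) -> tuple:
    # lexicographic cascade: group, short-term-recovery comorbidity absent,
    # younger age, essential function, actual score; lottery handled by caller
    return (
        result.priority_group,
        profile.short_term_recovery_comorbidity,
        profile.age_years,
        not profile.essential_function,
        result.priority_score,
    )


def tiebreak_compare(
    a: tuple[TriageResult, TiebreakProfile],
    b: tuple[TriageResult, TiebreakProfile],
) -> Ordering:
    """Compare two patients under the tiebreak cascade.

    Order: lower priority group first; absence of a comorbidity known to
    affect short-term recovery first; younger first; essential health-care
    function first; lower actual priority score first.  Patients identical
    on all five keys are a ``tie`` (resolved by lottery in
    :func:`allocate`).
    """
    ka, kb = _tiebreak_key(*a), _tiebreak_key(*b)
    if ka < kb:
        return Ordering.A_FIRST
    if kb < ka:
        return Ordering.B_FIRST
    return Ordering.TIE


def allocate(
    cohort_day: Sequence[tuple],
    n_resources: int,
    seed: int,
) -> list:
    """Allocate ``n_resources`` scarce resources for one cohort-day.

    ``cohort_day`` is a sequence of ``(patient_id, TriageResult,
    TiebreakProfile)``.  Patients are ranked by the tiebreak cascade;
    residual ties are broken by a uniform lottery seeded with ``seed``, so
    a rerun with the same seed reproduces the same allocation.  Returns the
    allocated patient ids in rank order.
    """
    if n_resources < 0:
        raise ValueError(f"n_resources must be non-negative, got {n_resources}")
    rng = np.random.default_rng(seed)
    lottery = rng.permutation(len(cohort_day))
    ranked = sorted(
        range(len(cohort_day)),
        key=lambda i: (_tiebreak_key(cohort_day[i][1], cohort_day[i][2]), lottery[i]),
    )
    take = min(n_resources, len(cohort_day))
    return [cohort_day[i][0] for i in ranked[:take]]


def score_table(
    patient_days,
    patients,
    catalog: Optional[ComorbidityCatalog] = None,
    group_map: Optional[Mapping[int, tuple]] = None,
):
    """Vectorised triage scoring of a patient-day table.

    ``patient_days`` needs ``patient_id`` and ``sofa_score`` columns;
    ``patients`` needs ``patient_id`` and a ``comorbidities`` column
    holding semicolon-joined catalog codes ("none" for documented absence).
    Returns a copy of ``patient_days`` with ``sofa_points``,
    ``comorbidity_points``, ``priority_score`` and ``priority_group``
    columns appended.
    """
    import pandas as pd

    catalog = catalog or ComorbidityCatalog.default()
    group_map = group_map or DEFAULT_GROUP_MAP

    sofa = patient_days["sofa_score"].to_numpy()
    valid = ~np.isnan(sofa.astype(float))
    if valid.any():
        lo, hi = np.nanmin(sofa), np.nanmax(sofa)
        if lo < 0 or hi > 24:
            raise ValueError(f"SOFA scores outside [0, 24]: range {lo}-{hi}")

    cpoints = patients.set_index("patient_id")["comorbidities"].map(
        lambda v: np.nan
        if (v is None or (isinstance(v, float) and np.isnan(v)) or v == "")
        else comorbidity_points(
            [] if v == "none" else str(v).split(";"), catalog
        )
    )

    out = patient_days.copy()
    spts = np.where(
        valid, 1 + np.searchsorted(SOFA_POINT_CUTS, sofa, side="right"), np.nan
    )
    out["sofa_points"] = spts
    out["comorbidity_points"] = out["patient_id"].map(cpoints).to_numpy()
    score = out["sofa_points"] + out["comorbidity_points"]
    out["priority_score"] = score
    edges = np.full(9, np.nan)
    for g, (glo, ghi) in group_map.items():
        for s in range(glo, ghi + 1):
            edges[s] = g
    grp = np.full(len(out), np.nan)
    ok = score.notna().to_numpy()
    grp[ok] = edges[score.to_numpy()[ok].astype(int)]
    out["priority_group"] = grp
    return out
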
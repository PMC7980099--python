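"""Disparity audit of triage priority scoring.

The audit asks whether self-identified race or ethnicity is associated
with the triage priority score a patient would receive under the
crisis-standards-of-care allocation policy.  It comprises:

* descriptive comparisons of patient characteristics across priority
  groups (chi-square for categorical rows, Kruskal-Wallis for continuous);
* eight multivariable Poisson regression models — one per outcome (max and
  min of priority score, priority group, SOFA score, SOFA points) — each
  containing both exposures (race and ethnicity) plus sex, preferred
  language, zip-code income band, primary insurer, age (continuous),
  COVID-unit admission, and hospital; associations are reported as
  incidence rate ratios (IRR = exponentiated coefficient) with Wald 95%
  confidence intervals;
* two sensitivity families: retaining "Unknown" as an explicit level for
  every categorical covariate (no patients dropped), and refitting without
  the socioeconomic covariates (income band, insurer);
* a reprioritization analysis comparing each patient's triage group under
  SOFA points alone against the full comorbidity-inclusive priority group.

The primary models are complete-case: a patient is dropped if any model
covariate is Unknown or missing.  Tiebreaker factors (short-term-recovery
comorbidity, age-as-tiebreak, essential function) are deliberately not
part of the audit.

Organised as a model/results pair: build a :class:`DisparityAudit` from a
cohort, call :meth:`~DisparityAudit.fit`, and read estimates, confidence
intervals and diagnostics off the returned :class:`DisparityAuditResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import OUTCOMES, ExclusionLog, apply_exclusions, summarize_patients
from .scoring import ComorbidityCatalog, score_table, sofa_only_group

__all__ = [
    "CATEGORICAL_COVARIATES",
    "DisparityAudit",
    "DisparityAuditResults",
    "chi_square",
    "descriptive_tests",
    "fit_irr_model",
    "sensitivity_unknown_category",
    "sensitivity_no_ses",
    "reprioritization",
]

#: categorical model covariates: name -> (reference level, known levels)
CATEGORICAL_COVARIATES = {
    "race": ("White", ["White", "Black", "Asian", "Multiracial"]),
    "ethnicity": ("Non-Hispanic", ["Non-Hispanic", "Hispanic"]),
    "sex": ("Male", ["Male", "Female"]),
    "language": ("English", ["English", "Spanish", "Other"]),
    "income_band": ("<25k", ["<25k", "25-<50k", "50-<75k", ">=75k"]),
    "insurer": ("Medicare/Medicaid", ["Medicare/Medicaid", "Commercial", "None"]),
    "hospital": ("tertiary", ["tertiary", "quaternary"]),
}
SES_COVARIATES = ("income_band", "insurer")
UNKNOWN = "Unknown"


def chi_square(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on an r x c count
    table; all-zero rows/columns are dropped first.  Returns (stat, p);
    (nan, nan) if fewer than two non-empty rows or columns remain."""
    t = np.asarray(table, dtype=float)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return float("nan"), float("nan")
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# descriptive comparisons


def descriptive_tests(
    summaries: pd.DataFrame,
    covariates: pd.DataFrame,
    grouping: str = "max",
    categorical: Sequence[str] = (
        "race",
        "ethnicity",
        "sex",
        "language",
        "income_band",
        "insurer",
        "has_5yr_comorbidity",
        "has_1yr_comorbidity",
        "covid_unit",
    ),
    continuous: Sequence[str] = ("age_years", "n_days"),
) -> pd.DataFrame:
    """Compare characteristics across priority groups.

    Categorical rows get a chi-square test over the full group cross-table
    (Unknown retained as a level); continuous rows get Kruskal-Wallis.
    A second column tests group 3 against group 1 only.  Degenerate tables
    are flagged rather than raised.
    """
    if grouping not in ("max", "min"):
        raise ValueError("grouping must be 'max' or 'min'")
    gcol = f"{grouping}_priority_group"
    data = summaries.merge(covariates, on="patient_id", validate="1:1")
    if data[gcol].nunique() < 2:
        raise ValueError("need at least 2 non-empty priority groups")
    groups = sorted(data[gcol].unique())
    extreme = data[data[gcol].isin([1, 3])]

    rows = []
    for var in categorical:
        if var not in data.columns:
            continue
        vals = data[var].fillna(UNKNOWN)
        table = pd.crosstab(vals, data[gcol]).to_numpy()
        stat, p = chi_square(table)
        t31 = pd.crosstab(
            extreme[var].fillna(UNKNOWN), extreme[gcol]
        ).to_numpy()
        _, p31 = chi_square(t31)
        rows.append(
            {
                "variable": var,
                "test": "chi2",
                "statistic": stat,
                "p_all_groups": p,
                "p_group3_vs_1": p31,
                "degenerate": bool(np.isnan(p) or np.isnan(p31)),
            }
        )
    for var in continuous:
        if var not in data.columns:
            continue
        samples = [
            data.loc[data[gcol] == g, var].dropna().to_numpy() for g in groups
        ]
        samples = [s for s in samples if len(s)]
        try:
            stat, p = stats.kruskal(*samples)
        except ValueError:  # identical values or a single group
            stat, p = float("nan"), float("nan")
        s3 = extreme.loc[extreme[gcol] == 3, var].dropna()
        s1 = extreme.loc[extreme[gcol] == 1, var].dropna()
        try:
            _, p31 = stats.kruskal(s1, s3)
        except ValueError:
            p31 = float("nan")
        rows.append(
            {
                "variable": var,
                "test": "kruskal",
                "statistic": float(stat),
                "p_all_groups": float(p),
                "p_group3_vs_1": float(p31),
                "degenerate": bool(np.isnan(p) or np.isnan(p31)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Poisson IRR models


def _design_matrix(
    data: pd.DataFrame,
    unknown_as_category: bool,
    drop_ses: bool,
) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Build the regression design.  Returns (rows used, X, row metadata)."""
    cats = {
        k: v for k, v in CATEGORICAL_COVARIATES.items()
        if not (drop_ses and k in SES_COVARIATES)
    }
    d = data.copy()
    for var in cats:
        d[var] = d[var].fillna(UNKNOWN)
    if unknown_as_category:
        d["age_years"] = d["age_years"].fillna(d["age_years"].median())
    else:
        keep = d["age_years"].notna()
        for var in cats:
            keep &= d[var] != UNKNOWN
        d = d[keep]

    X = pd.DataFrame({"const": np.ones(len(d))}, index=d.index)
    meta = [{"covariate": "const", "level": "", "reference": False}]
    for var, (ref, levels) in cats.items():
        all_levels = list(levels) + ([UNKNOWN] if unknown_as_category else [])
        meta.append({"covariate": var, "level": ref, "reference": True})
        for lev in all_levels:
            if lev == ref:
                continue
            col = (d[var] == lev).astype(float)
            if col.sum() == 0:
                warnings.warn(
                    f"covariate {var!r} level {lev!r} empty after filtering; dropped",
                    stacklevel=3,
                )
                continue
            X[f"{var}[{lev}]"] = col
            meta.append({"covariate": var, "level": lev, "reference": False})
    X["age_years"] = d["age_years"].astype(float)
    meta.append({"covariate": "age_years", "level": "per year", "reference": False})
    X["covid_unit"] = d["covid_unit"].astype(float)
    meta.append({"covariate": "covid_unit", "level": "yes", "reference": False})
    return d, X, meta


def _check_collinearity(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank == arr.shape[1]:
        return
    # greedily identify the offending columns
    bad, kept = [], []
    for j, name in enumerate(X.columns):
        trial = kept + [j]
        if np.linalg.matrix_rank(arr[:, trial]) == len(trial):
            kept.append(j)
        else:
            bad.append(name)
    raise ValueError(f"perfectly collinear covariates: {bad}")


def fit_irr_model(
    summaries: pd.DataFrame,
    covariates: pd.DataFrame,
    outcome: str,
    *,
    unknown_as_category: bool = False,
    drop_ses: bool = False,
    robust: bool = False,
) -> pd.DataFrame:
    """Multivariable Poisson regression of one per-patient outcome.

    Returns an IRR table: one row per covariate level with the incidence
    rate ratio, Wald 95% CI and p-value; reference levels carry IRR 1 and
    ``reference=True``.  ``robust=True`` switches to sandwich (HC0)
    standard errors, appropriate when the outcome is a bounded score
    rather than a true count.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}, got {outcome!r}")
    data = summaries.merge(covariates, on="patient_id", validate="1:1")
    d, X, meta = _design_matrix(data, unknown_as_category, drop_ses)
    if len(d) == 0:
        raise ValueError("no complete-case patients left to fit")
    _check_collinearity(X)
    y = d[outcome].astype(float)

    model = sm.GLM(y, X, family=sm.families.Poisson())
    try:
        res = model.fit(cov_type="HC0" if robust else "nonrobust")
    except Exception as err:  # pragma: no cover - surfaced to CLI as exit 3
        raise RuntimeError(f"Poisson model failed for {outcome}: {err}") from err

    ci = res.conf_int()
    rows = []
    for m in meta:
        if m["covariate"] == "const":
            continue
        if m["reference"]:
            rows.append(
                {
                    "outcome": outcome,
                    "covariate": m["covariate"],
                    "level": m["level"],
                    "irr": 1.0,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p_value": np.nan,
                    "reference": True,
                }
            )
            continue
        name = (
            m["covariate"]
            if m["covariate"] in ("age_years", "covid_unit")
            else f"{m['covariate']}[{m['level']}]"
        )
        rows.append(
            {
                "outcome": outcome,
                "covariate": m["covariate"],
                "level": m["level"],
                "irr": float(np.exp(res.params[name])),
                "ci_low": float(np.exp(ci.loc[name, 0])),
                "ci_high": float(np.exp(ci.loc[name, 1])),
                "p_value": float(res.pvalues[name]),
                "reference": False,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["n_patients"] = int(len(d))
    table.attrs["robust"] = robust
    return table


def sensitivity_unknown_category(
    summaries: pd.DataFrame,
    covariates: pd.DataFrame,
    outcome: str,
    *,
    robust: bool = False,
) -> pd.DataFrame:
    """Sensitivity analysis: all patients retained, Unknown kept as an
    explicit level for every categorical covariate."""
    return fit_irr_model(
        summaries, covariates, outcome, unknown_as_category=True, robust=robust
    )


def sensitivity_no_ses(
    summaries: pd.DataFrame,
    covariates: pd.DataFrame,
    outcome: str,
    *,
    robust: bool = False,
) -> pd.DataFrame:
    """Sensitivity analysis excluding the socioeconomic covariates (zip-code
    income band and primary insurer), which may themselves track race or
    ethnicity."""
    return fit_irr_model(summaries, covariates, outcome, drop_ses=True, robust=robust)


# ---------------------------------------------------------------------------
# reprioritization (comorbidity-inclusion) analysis


def reprioritization(
    summaries: pd.DataFrame,
    covariates: pd.DataFrame,
    which: str = "max",
) -> pd.DataFrame:
    """Fraction of patients whose triage group moves when comorbidity
    points are included.

    For each patient the 3-level SOFA-points-only group is compared with
    the full priority group at the chosen extremum: "higher" means the
    full-algorithm group index is strictly smaller (better priority),
    "lower" strictly larger.  Fractions are reported per race level, per
    ethnicity level, and overall.
    """
    if which not in ("max", "min"):
        raise ValueError("which must be 'max' or 'min'")
    data = summaries.merge(covariates, on="patient_id", validate="1:1")
    sofa_grp = data[f"{which}_sofa_points"].map(sofa_only_group)
    full_grp = data[f"{which}_priority_group"]
    move = np.where(
        full_grp < sofa_grp, "higher", np.where(full_grp > sofa_grp, "lower", "unchanged")
    )
    data = data.assign(_move=move)

    rows = []

    def _frac(sub: pd.DataFrame, covariate: str, level: str) -> None:
        n = len(sub)
        counts = sub["_move"].value_counts()
        rows.append(
            {
                "covariate": covariate,
                "level": level,
                "n": n,
                "frac_higher": counts.get("higher", 0) / n,
                "frac_lower": counts.get("lower", 0) / n,
                "frac_unchanged": counts.get("unchanged", 0) / n,
            }
        )

    _frac(data, "overall", "all")
    for var in ("race", "ethnicity"):
        for level, sub in data.groupby(data[var].fillna(UNKNOWN)):
            _frac(sub, var, str(level))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results


class DisparityAudit:
    """Equity audit model for a scored triage cohort.

    Parameters
    ----------
    summaries : DataFrame
        Per-patient outcome extrema from
        :func:`csctriage.cohort.summarize_patients`.
    covariates : DataFrame
        One row per patient with the model covariates (race, ethnicity,
        sex, language, income_band, insurer, age_years, covid_unit,
        hospital) and optionally the comorbidity flags used in
        descriptive rows.
    exclusion_log : ExclusionLog, optional
        Carried through to the results for reporting.

    Use :meth:`from_cohort` to build directly from raw patient and
    patient-day tables (scoring and exclusions applied internally), then
    call :meth:`fit`.
    """

    def __init__(
        self,
        summaries: pd.DataFrame,
        covariates: pd.DataFrame,
        exclusion_log: Optional[ExclusionLog] = None,
    ) -> None:
        ids_s = set(summaries["patient_id"])
        ids_c = set(covariates["patient_id"])
        if not ids_s <= ids_c:
            raise ValueError(
                f"{len(ids_s - ids_c)} summarised patients lack covariate rows"
            )
        self.summaries = summaries.reset_index(drop=True)
        self.covariates = (
            covariates[covariates["patient_id"].isin(ids_s)].reset_index(drop=True)
        )
        self.exclusion_log = exclusion_log or ExclusionLog()

    @classmethod
    def from_cohort(
        cls,
        patients: pd.DataFrame,
        patient_days: pd.DataFrame,
        catalog: Optional[ComorbidityCatalog] = None,
        group_map: Optional[Mapping[int, tuple]] = None,
    ) -> "DisparityAudit":
        """Score a raw cohort, apply the exclusion rules, and summarise."""
        catalog = catalog or ComorbidityCatalog.default()
        days, kept, log = apply_exclusions(patient_days, patients)
        scored = score_table(days, kept, catalog=catalog, group_map=group_map)
        summaries = summarize_patients(scored)
        cov = kept.copy()
        codes = cov["comorbidities"].map(
            lambda v: [] if v == "none" else str(v).split(";")
        )
        tiers = codes.map(lambda cs: {catalog.tier_of(c).value for c in cs})
        cov["has_5yr_comorbidity"] = tiers.map(lambda t: "five_year" in t)
        cov["has_1yr_comorbidity"] = tiers.map(lambda t: "one_year" in t)
        return cls(summaries, cov, exclusion_log=log)

    @property
    def n_patients(self) -> int:
        return len(self.summaries)

    def fit(
        self,
        outcomes: Optional[Sequence[str]] = None,
        *,
        robust: bool = False,
        sensitivities: bool = True,
        descriptives: bool = True,
    ) -> "DisparityAuditResults":
        """Fit the Poisson IRR models (and, by default, the sensitivity
        variants, descriptive tests and reprioritization analysis)."""
        outcomes = list(outcomes) if outcomes is not None else list(OUTCOMES)
        irr = {
            o: fit_irr_model(self.summaries, self.covariates, o, robust=robust)
            for o in outcomes
        }
        irr_unknown = irr_no_ses = None
        if sensitivities:
            irr_unknown = {
                o: sensitivity_unknown_category(
                    self.summaries, self.covariates, o, robust=robust
                )
                for o in outcomes
            }
            irr_no_ses = {
                o: sensitivity_no_ses(self.summaries, self.covariates, o, robust=robust)
                for o in outcomes
            }
        desc = None
        if descriptives:
            desc = {
                w: descriptive_tests(self.summaries, self.covariates, grouping=w)
                for w in ("max", "min")
            }
        reprio = {
            w: reprioritization(self.summaries, self.covariates, which=w)
            for w in ("max", "min")
        }
        return DisparityAuditResults(
            model=self,
            irr=irr,
            irr_unknown_sensitivity=irr_unknown,
            irr_no_ses_sensitivity=irr_no_ses,
            descriptives=desc,
            reprioritization=reprio,
            robust=robust,
        )


@dataclass
class DisparityAuditResults:
    """Fitted audit: IRR tables, sensitivity variants, descriptives and the
    reprioritization cross-tabulation."""

    model: DisparityAudit
    irr: Mapping[str, pd.DataFrame]
    irr_unknown_sensitivity: Optional[Mapping[str, pd.DataFrame]]
    irr_no_ses_sensitivity: Optional[Mapping[str, pd.DataFrame]]
    descriptives: Optional[Mapping[str, pd.DataFrame]]
    reprioritization: Mapping[str, pd.DataFrame]
    robust: bool = False
    _extra: dict = dc_field(default_factory=dict)

    def irr_for(
        self, outcome: str, covariate: str, level: str
    ) -> tuple[float, float, float]:
        """(IRR, CI low, CI high) for one covariate level of one outcome."""
        t = self.irr[outcome]
        row = t[(t["covariate"] == covariate) & (t["level"] == level)]
        if len(row) != 1:
            raise KeyError(f"no unique IRR row for {covariate}={level}")
        r = row.iloc[0]
        return float(r["irr"]), float(r["ci_low"]), float(r["ci_high"])

    def summary(self) -> str:
        """Human-readable report in journal style (IRR to 2 decimals)."""
        from .io import format_irr, format_p

        lines = [
            "Disparity audit of CSC triage priority scoring",
            "=" * 46,
            f"Patients analysed: {self.model.n_patients}",
            f"Standard errors: {'robust (HC0 sandwich)' if self.robust else 'model-based Wald'}",
            "",
            "Exclusions: "
            + ", ".join(f"{k}={v}" for k, v in self.model.exclusion_log.as_dict().items()),
            "",
        ]
        for outcome, table in self.irr.items():
            lines.append(f"Outcome: {outcome}  (n={table.attrs.get('n_patients', '?')})")
            for _, r in table.iterrows():
                if r["reference"]:
                    lines.append(f"  {r['covariate']:<12} {r['level']:<18} 1 [Reference]")
                else:
                    lines.append(
                        f"  {r['covariate']:<12} {r['level']:<18} "
                        f"{format_irr(r['irr'], r['ci_low'], r['ci_high'])}"
                        f"  P={format_p(r['p_value'])}"
                    )
            lines.append("")
        for which, table in self.reprioritization.items():
            lines.append(f"Reprioritization ({which} extremum): ")
            for _, r in table.iterrows():
                lines.append(
                    f"  {r['covariate']:<10} {r['level']:<14} "
                    f"higher {100 * r['frac_higher']:.0f}%  "
                    f"lower {100 * r['frac_lower']:.0f}%  "
                    f"unchanged {100 * r['frac_unchanged']:.0f}%"
                )
            lines.append("")
        return "\n".join(lines)
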
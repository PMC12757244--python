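"""Case/non-case logistic regression within the target-drug cohort.

Within reports naming the target drug as primary suspect, cases (target
event) are contrasted with non-cases (any other event) via logistic
regression on sex, age band, regimen and co-drug indicators.  The
workflow mirrors standard pharmacovigilance practice: complete-case
filtering, a univariate screen at P < 0.20 (with a configurable
force-include set — age is force-included by default to address
baseline confounding even when the screen misses it), then one joint
maximum-likelihood fit.  Odds-ratio CIs are Wald; per-variable P values
come from likelihood-ratio tests against the nested model without that
variable.

Fitting is delegated to statsmodels (Newton-Raphson, tolerance 1e-8,
iteration cap 100).  Separation is flagged when a fitted coefficient
exceeds 15 on the logit scale; a flagged variable is excluded from the
multivariate model with a warning.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .faers_core import (
    REGIMEN_Q4W_120,
    REGIMEN_Q6M_60,
    EventLabel,
    ExposureSpec,
    Report,
    normalize_name,
)

logger = logging.getLogger("faerspv")

SEPARATION_COEF_LIMIT = 15.0
MAXITER = 100
TOL = 1e-8
Z_95 = 1.96


class UnfittableError(ValueError):
    """Raised when the analysis frame is empty or single-class."""


def covariate_column(co_drug: str) -> str:
    """Column name for a co-drug indicator (``co_zoledronic_acid``)."""
    return "co_" + re.sub(r"\W+", "_", normalize_name(co_drug)).strip("_")


@dataclass
class CovariateSpec:
    """Which covariates enter the model."""

    sex: bool = True
    age: bool = True
    dose: bool = True
    co_drugs: tuple = ()
    age_cut: float = 65.0

    def columns(self) -> list[str]:
        cols = []
        if self.sex:
            cols.append("sex_male")
        if self.age:
            cols.append("age_ge_65")
        if self.dose:
            cols.append("high_dose")
        cols.extend(covariate_column(c) for c in self.co_drugs)
        return cols


def build_frame(
    reports: Sequence[Report],
    cohort: ExposureSpec,
    event: EventLabel,
    covariates: CovariateSpec,
) -> tuple[pd.DataFrame, dict]:
    """Complete-case analysis frame for the cohort, plus an exclusion tally.

    Cohort membership requires the target drug with the cohort's role.
    A report missing any required covariate (sex, age, or a regimen that
    is neither 60 mg Q6m nor 120 mg Q4w) is dropped; the tally counts
    each missing field among dropped reports (a report may appear under
    several fields).  Co-drug indicators are presence flags and are
    never missing.
    """
    target = normalize_name(cohort.target_drug)
    tally = {"not_in_cohort": 0, "sex": 0, "age": 0, "dose": 0, "dropped": 0}
    rows = []
    for r in reports:
        entries = [
            d
            for d in r.drugs
            if normalize_name(d.name_std) == target
            and (cohort.required_role == "any" or d.role == cohort.required_role)
        ]
        if not entries:
            tally["not_in_cohort"] += 1
            continue
        missing = []
        if covariates.sex and r.sex is None:
            missing.append("sex")
        if covariates.age and r.age_years is None:
            missing.append("age")
        regimens = {d.regimen for d in entries} - {None}
        dichotomous = regimens & {REGIMEN_Q6M_60, REGIMEN_Q4W_120}
        if covariates.dose and not dichotomous:
            missing.append("dose")
        if missing:
            for m in missing:
                tally[m] += 1
            tally["dropped"] += 1
            continue
        present = r.drug_names_std()
        row = {"outcome": int(r.has_event(event))}
        if covariates.sex:
            row["sex_male"] = int(r.sex == "male")
        if covariates.age:
            row["age_ge_65"] = int(r.age_years >= covariates.age_cut)
        if covariates.dose:
            row["high_dose"] = int(REGIMEN_Q4W_120 in dichotomous)
        for cd in covariates.co_drugs:
            row[covariate_column(cd)] = int(normalize_name(cd) in present)
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["outcome"] + covariates.columns())
    return frame, tally


def _check_fittable(frame: pd.DataFrame) -> None:
    if frame.empty:
        raise UnfittableError("analysis frame is empty")
    if frame["outcome"].nunique() < 2:
        raise UnfittableError("outcome has a single class; model is unfittable")


def _wald_or_ci(coef: float, se: float, z: float = Z_95) -> tuple:
    # exponent clipped: a separated variable would otherwise overflow exp
    lo = float(np.exp(min(coef - z * se, 700.0)))
    hi = float(np.exp(min(coef + z * se, 700.0)))
    return (lo, hi)


def _fit_logit(y: np.ndarray, X: np.ndarray):
    model = sm.Logit(y, X)
    return model.fit(method="newton", maxiter=MAXITER, tol=TOL, disp=False)


@dataclass
class VariableResult:
    """Crude and adjusted estimates for one covariate."""

    name: str
    crude_or: float = np.nan
    crude_ci: tuple = (np.nan, np.nan)
    crude_p: float = np.nan
    screen_included: bool = False
    separation: bool = False
    adjusted_or: float = np.nan
    adjusted_ci: tuple = (np.nan, np.nan)
    adjusted_p: float = np.nan


@dataclass
class LogisticResult:
    """Full univariate + multivariate output (Table-2 shape)."""

    variables: dict = field(default_factory=dict)  # name -> VariableResult
    n: int = 0
    n_cases: int = 0
    log_likelihood: float = np.nan
    converged: bool = True
    included: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.variables.values():
            rows.append(
                {
                    "variable": v.name,
                    "crude_or": v.crude_or,
                    "crude_ci_low": v.crude_ci[0],
                    "crude_ci_high": v.crude_ci[1],
                    "crude_p": v.crude_p,
                    "screen_included": v.screen_included,
                    "separation": v.separation,
                    "adjusted_or": v.adjusted_or,
                    "adjusted_ci_low": v.adjusted_ci[0],
                    "adjusted_ci_high": v.adjusted_ci[1],
                    "adjusted_p": v.adjusted_p,
                }
            )
        return pd.DataFrame(rows)


def univariate_screen(
    frame: pd.DataFrame,
    alpha_screen: float = 0.20,
    force_include: frozenset | set = frozenset({"age_ge_65"}),
) -> dict[str, VariableResult]:
    """One single-covariate logistic fit per variable.

    Crude OR = exp(coefficient) with a Wald CI; P from the likelihood-
    ratio test against the intercept-only model.  ``screen_included`` is
    true when P < alpha_screen or the variable is in the force list.
    Variables with separation are flagged and excluded from the
    multivariate stage.
    """
    _check_fittable(frame)
    y = frame["outcome"].to_numpy(float)
    results: dict[str, VariableResult] = {}
    for name in [c for c in frame.columns if c != "outcome"]:
        vr = VariableResult(name=name)
        x = frame[name].to_numpy(float)
        if np.all(x == x[0]):
            vr.separation = True  # constant column: no information
            vr.screen_included = False
            results[name] = vr
            continue
        X = sm.add_constant(x)
        try:
            fit = _fit_logit(y, X)
        except Exception:  # pragma: no cover - pathological design
            vr.separation = True
            results[name] = vr
            continue
        coef = fit.params[1]
        se = fit.bse[1]
        lrt = 2.0 * (fit.llf - fit.llnull)
        vr.crude_p = float(stats.chi2.sf(max(lrt, 0.0), df=1))
        vr.crude_or = float(np.exp(coef))
        vr.crude_ci = _wald_or_ci(coef, se)
        if abs(coef) > SEPARATION_COEF_LIMIT:
            vr.separation = True
            logger.warning("separation detected for %s (|coef|=%.1f)", name, coef)
        vr.screen_included = (
            not vr.separation
            and (vr.crude_p < alpha_screen or name in force_include)
        )
        results[name] = vr
    return results


def _drop_collinear(frame: pd.DataFrame, included: list[str]) -> list[str]:
    """Greedily drop variables that make the design rank-deficient."""
    kept: list[str] = []
    for name in included:
        cols = kept + [name]
        X = np.column_stack([np.ones(len(frame))] + [frame[c] for c in cols])
        if np.linalg.matrix_rank(X) == X.shape[1]:
            kept.append(name)
        else:
            logger.warning("dropping collinear variable %s", name)
    return kept


def multivariate_fit(
    frame: pd.DataFrame, included: Sequence[str]
) -> LogisticResult:
    """Joint maximum-likelihood fit over the included variables.

    Adjusted OR = exp(coefficient) with a Wald CI; per-variable P from
    the likelihood-ratio test comparing the full model with the model
    omitting that variable.
    """
    if not included:
        raise ValueError("included variable set must be non-empty")
    _check_fittable(frame)
    included = _drop_collinear(frame, list(included))
    y = frame["outcome"].to_numpy(float)
    X = np.column_stack([np.ones(len(frame))] + [frame[c] for c in included])
    fit = _fit_logit(y, X)
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError(
            f"multivariate fit did not converge in {MAXITER} iterations "
            f"(llf={fit.llf:.3f})"
        )
    result = LogisticResult(
        n=len(frame),
        n_cases=int(frame["outcome"].sum()),
        log_likelihood=float(fit.llf),
        included=tuple(included),
    )
    for j, name in enumerate(included, start=1):
        coef = fit.params[j]
        se = fit.bse[j]
        vr = VariableResult(name=name, screen_included=True)
        vr.adjusted_or = float(np.exp(coef))
        vr.adjusted_ci = _wald_or_ci(coef, se)
        rest = [c for c in included if c != name]
        if rest:
            X_red = np.column_stack(
                [np.ones(len(frame))] + [frame[c] for c in rest]
            )
        else:
            X_red = np.ones((len(frame), 1))
        fit_red = _fit_logit(y, X_red)
        lrt = 2.0 * (fit.llf - fit_red.llf)
        vr.adjusted_p = float(stats.chi2.sf(max(lrt, 0.0), df=1))
        result.variables[name] = vr
    return result


def logistic_table(
    frame: pd.DataFrame,
    alpha_screen: float = 0.20,
    force_include: frozenset | set = frozenset({"age_ge_65"}),
) -> LogisticResult:
    """Run the full screen-then-adjust workflow and merge the two stages.

    Variables screened out (or separated) keep their crude columns and
    leave the adjusted columns empty, preserving the published table
    shape.
    """
    crude = univariate_screen(frame, alpha_screen, force_include)
    included = [n for n, v in crude.items() if v.screen_included]
    result = LogisticResult(n=len(frame), n_cases=int(frame["outcome"].sum()))
    if included:
        adj = multivariate_fit(frame, included)
        result.log_likelihood = adj.log_likelihood
        result.included = adj.included
    else:
        adj = LogisticResult()
    for name, vr in crude.items():
        merged = VariableResult(
            name=name,
            crude_or=vr.crude_or,
            crude_ci=vr.crude_ci,
            crude_p=vr.crude_p,
            screen_included=vr.screen_included,
            separation=vr.separation,
        )
        if name in adj.variables:
            a = adj.variables[name]
            merged.adjusted_or = a.adjusted_or
            merged.adjusted_ci = a.adjusted_ci
            merged.adjusted_p = a.adjusted_p
        result.variables[name] = merged
    return result
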
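"""Reporting odds ratio (ROR) disproportionality analysis.

The case/non-case design contrasts reports of the target event against
all other adverse-event reports.  For an exposure E and event Y the 2x2
table is

    a = exposed reports with the event        (target drug, target event)
    b = unexposed reports with the event      (all other drugs, target event)
    c = exposed reports with other events
    d = unexposed reports with other events

ROR = (a/c)/(b/d), with the log-Wald 95% interval
exp(ln ROR ± z * sqrt(1/a + 1/b + 1/c + 1/d)).  A signal is declared
when the interval's lower bound exceeds 1 and there are at least three
exposed cases.  Zero cells yield an explicit undefined-ROR sentinel
rather than a continuity correction, keeping published-style estimates
untouched and the classifiable total conserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .faers_core import (
    CLASS_EXPOSED_CASE,
    CLASS_EXPOSED_NONCASE,
    CLASS_NOT_CLASSIFIABLE,
    CLASS_UNEXPOSED_CASE,
    EventLabel,
    ExposureSpec,
    Report,
    classify_report,
)

Z_95 = 1.96


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """2x2 counts underlying one disproportionality estimate."""

    a: int  # exposed cases
    b: int  # other-drug reports with the event
    c: int  # exposed non-cases
    d: int  # other-drug reports with other events
    n_not_classifiable: int = 0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def total_classifiable(self) -> int:
        return self.a + self.b + self.c + self.d

    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


@dataclass(frozen=True, slots=True)
class RorResult:
    """ROR point estimate with log-Wald CI and the signal flag.

    ``defined`` is False when any cell is zero; the table is carried so
    the caller can see why.
    """

    table: ContingencyTable
    ror: float
    ci_low: float
    ci_high: float
    n_cases: int
    is_signal: bool
    defined: bool
    exposure: ExposureSpec | None = None

    @property
    def label(self) -> str:
        return self.exposure.describe() if self.exposure else ""


def contingency(
    reports: Sequence[Report], exposure: ExposureSpec, event: EventLabel
) -> ContingencyTable:
    """Tally the 2x2 table over deduplicated reports.

    One report contributes to exactly one cell (or to the not-classifiable
    tally when a filter references a field it is missing).
    """
    a = b = c = d = nc = 0
    for r in reports:
        cls = classify_report(r, exposure, event)
        if cls == CLASS_EXPOSED_CASE:
            a += 1
        elif cls == CLASS_EXPOSED_NONCASE:
            c += 1
        elif cls == CLASS_UNEXPOSED_CASE:
            b += 1
        elif cls == CLASS_NOT_CLASSIFIABLE:
            nc += 1
        else:
            d += 1
    return ContingencyTable(a=a, b=b, c=c, d=d, n_not_classifiable=nc)


def ror(
    table: ContingencyTable,
    z: float = Z_95,
    exposure: ExposureSpec | None = None,
    min_cases: int = 3,
) -> RorResult:
    """Point estimate, CI and signal flag for one 2x2 table."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if table.has_zero_cell():
        return RorResult(
            table=table,
            ror=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            n_cases=a,
            is_signal=False,
            defined=False,
            exposure=exposure,
        )
    estimate = (a / c) / (b / d)
    se_log = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = math.exp(math.log(estimate) - z * se_log)
    ci_high = math.exp(math.log(estimate) + z * se_log)
    return RorResult(
        table=table,
        ror=estimate,
        ci_low=ci_low,
        ci_high=ci_high,
        n_cases=a,
        is_signal=(ci_low > 1.0) and (a >= min_cases),
        defined=True,
        exposure=exposure,
    )


def analyze_exposure(
    reports: Sequence[Report],
    exposure: ExposureSpec,
    event: EventLabel,
    z: float = Z_95,
) -> RorResult:
    """Convenience: contingency + ror in one call."""
    return ror(contingency(reports, exposure, event), z=z, exposure=exposure)


def stratified_rors(
    reports: Sequence[Report],
    base_exposure: ExposureSpec,
    event: EventLabel,
    strata: Sequence[ExposureSpec],
    z: float = Z_95,
) -> list[RorResult]:
    """One ROR per stratum, each against the full all-other-drugs comparator.

    Each stratum must be a refinement of the base exposure (same target
    drug and role); reports missing the stratifying field are excluded
    from that stratum's table only.
    """
    for s in strata:
        if (
            s.target_drug.casefold() != base_exposure.target_drug.casefold()
            or s.required_role != base_exposure.required_role
        ):
            raise ValueError(
                f"stratum {s.describe()!r} is not a refinement of the base exposure"
            )
    return [analyze_exposure(reports, s, event, z=z) for s in strata]


def default_strata(base: ExposureSpec) -> list[ExposureSpec]:
    """The standard stratification set: age band, sex, regimen."""
    return [
        base.refine(age_max=65.0, label="age<65"),
        base.refine(age_min=65.0, label="age>=65"),
        base.refine(sex="male", label="male"),
        base.refine(sex="female", label="female"),
        base.refine(regimen_filter="q6m_60mg", label="60mg_q6m"),
        base.refine(regimen_filter="q4w_120mg", label="120mg_q4w"),
    ]


def results_to_frame(results: Sequence[RorResult]) -> pd.DataFrame:
    """Flat table: one row per exposure/stratum (export / forest-plot input)."""
    rows = []
    for r in results:
        rows.append(
            {
                "label": r.label,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "not_classifiable": r.table.n_not_classifiable,
                "ror": r.ror,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "n_cases": r.n_cases,
                "is_signal": r.is_signal,
                "defined": r.defined,
            }
        )
    return pd.DataFrame(rows)


def write_forest_file(results: Sequence[RorResult], path) -> None:
    """Label/estimate/CI file ready for a forest plot."""
    df = results_to_frame(results)[["label", "ror", "ci_low", "ci_high"]]
    df.to_csv(path, index=False, float_format="%.6g")
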
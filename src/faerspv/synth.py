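"""Synthetic FAERS-like data with known ground truth.

The generator plants every quantity the downstream analyses estimate, so
parameter recovery can be tested without external data:

* a case/non-case structure with a known marginal reporting odds ratio
  for the target drug (the event indicator follows a logistic model over
  sex, age band, regimen and co-drug indicators among exposed reports,
  and a background rate elsewhere);
* Weibull-distributed therapy-to-onset latencies per regimen stratum;
* structured missingness in age / sex / dose text / reporter, applied
  only after the latent truth is recorded;
* duplicate report versions (earlier FDA receipt date or same date with
  a lower PRIMARYID) whose canonical survivors are recorded, so the
  deduplication rule can be checked exactly.

Default parameters emulate the reporting patterns of denosumab-related
osteonecrosis of the jaw in the public FAERS archive: roughly 0.9% of
reports name the drug, ~5% of those report the event, the 120 mg Q4w
oncology regimen carries a shorter Weibull scale and a larger shape than
the 60 mg Q6m osteoporosis regimen, and most case latencies are missing.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .faers_core import (
    REGIMEN_Q4W_120,
    REGIMEN_Q6M_60,
    DrugEntry,
    Report,
)

BACKGROUND_DRUGS = ("aspirin", "metformin", "lisinopril", "omeprazole")
BACKGROUND_EVENTS = ("Nausea", "Arthralgia", "Fatigue", "Dizziness", "Headache")
COUNTRIES = ("US", "JP", "DE", "CA", "GB")
COUNTRY_PROBS = (0.60, 0.12, 0.08, 0.08, 0.12)


@dataclass
class SynthConfig:
    """Generative parameters; the defaults are the study conditions.

    ``true_log_or`` drives the event model among exposed reports:
    logit P(event) = intercept + male + age_ge_65 + high_dose + co-drug
    terms.  ``latency_params`` maps regimen strata to Weibull
    (scale alpha in days, shape beta).  ``missing_rates['tto']`` is the
    fraction of exposed cases whose onset/therapy dates are masked.
    """

    n_reports: int = 50_000
    seed: int = 0
    target_drug: str = "denosumab"
    event_pt: str = "Osteonecrosis of jaw"
    event_pt_code: int | None = 10064658
    target_exposure_prob: float = 0.00916
    background_event_rate: float = 0.000943
    p_male: float = 0.131
    p_age_ge_65: float = 0.76
    p_high_dose: float = 0.30
    p_hcp: float = 0.673
    co_drug_probs: dict = field(
        default_factory=lambda: {"zoledronic acid": 0.0023, "prednisolone": 0.0019}
    )
    true_log_or: dict = field(
        default_factory=lambda: {
            "intercept": -3.9,
            "male": math.log(3.08),
            "age_ge_65": math.log(1.48),
            "high_dose": math.log(7.18),
            "zoledronic acid": math.log(10.80),
            "prednisolone": math.log(3.93),
        }
    )
    latency_params: dict = field(
        default_factory=lambda: {
            REGIMEN_Q6M_60: (712.83, 1.06),
            REGIMEN_Q4W_120: (576.47, 1.33),
        }
    )
    missing_rates: dict = field(
        default_factory=lambda: {
            "age": 0.41,
            "sex": 0.12,
            "dose": 0.44,
            "reporter": 0.009,
            "tto": 0.785,
        }
    )
    duplicate_rate: float = 0.10
    calendar_window: tuple = (dt.date(2010, 4, 1), dt.date(2024, 9, 30))

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        probs = [
            self.target_exposure_prob,
            self.background_event_rate,
            self.p_male,
            self.p_age_ge_65,
            self.p_high_dose,
            self.p_hcp,
            self.duplicate_rate,
            *self.co_drug_probs.values(),
            *self.missing_rates.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        for stratum, (alpha, beta) in self.latency_params.items():
            if alpha <= 0 or beta <= 0:
                raise ValueError(f"Weibull parameters must be positive ({stratum})")
        if self.calendar_window[0] >= self.calendar_window[1]:
            raise ValueError("calendar_window start must precede end")


@dataclass
class GroundTruth:
    """Latent truth recorded before masking; the oracle for recovery tests."""

    true_ror: float  # marginal reporting odds ratio of the target exposure
    true_or: dict  # conditional odds ratio per covariate
    strata: dict  # stratum -> dict(alpha, beta, median_days)
    canonical_primary_ids: frozenset
    report_truth: pd.DataFrame  # one row per canonical report, pre-masking
    config: SynthConfig


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _true_marginal_ror(config: SynthConfig) -> float:
    """Exact marginal ROR implied by the generative model.

    The exposed event probability is averaged over the joint distribution
    of the independent binary covariates; the marginal ROR is the odds of
    that average against the background odds.
    """
    lo = config.true_log_or
    covs = [
        ("male", config.p_male, lo.get("male", 0.0)),
        ("age_ge_65", config.p_age_ge_65, lo.get("age_ge_65", 0.0)),
        ("high_dose", config.p_high_dose, lo.get("high_dose", 0.0)),
    ] + [
        (name, p, lo.get(name, 0.0)) for name, p in config.co_drug_probs.items()
    ]
    p_event = 0.0
    for bits in product((0, 1), repeat=len(covs)):
        prob = 1.0
        eta = lo.get("intercept", 0.0)
        for bit, (_, p, coef) in zip(bits, covs):
            prob *= p if bit else (1.0 - p)
            eta += bit * coef
        p_event += prob / (1.0 + math.exp(-eta))
    p0 = config.background_event_rate
    return (p_event / (1.0 - p_event)) / (p0 / (1.0 - p0))


def generate(config: SynthConfig) -> tuple[list[Report], GroundTruth]:
    """Draw a synthetic report set and its ground truth.

    Fully deterministic for a fixed ``config.seed``.  Duplicate versions
    perturb only FDA receipt date, PRIMARYID and reporter, never the
    case's drugs or events, so the canonical set is well-defined.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    lo = config.true_log_or
    co_names = list(config.co_drug_probs)

    exposed = rng.random(n) < config.target_exposure_prob
    male = rng.random(n) < config.p_male
    age65 = rng.random(n) < config.p_age_ge_65
    age_years = np.where(
        age65,
        rng.uniform(65.0, 95.0, n),
        rng.uniform(18.0, 64.9, n),
    ).round(1)
    high_dose = (rng.random(n) < config.p_high_dose) & exposed
    co_flags = {
        name: (rng.random(n) < p) & exposed
        for name, p in config.co_drug_probs.items()
    }

    eta = np.full(n, lo.get("intercept", 0.0))
    eta += np.where(male, lo.get("male", 0.0), 0.0)
    eta += np.where(age65, lo.get("age_ge_65", 0.0), 0.0)
    eta += np.where(high_dose, lo.get("high_dose", 0.0), 0.0)
    for name in co_names:
        eta += np.where(co_flags[name], lo.get(name, 0.0), 0.0)
    p_event = np.where(exposed, _sigmoid(eta), config.background_event_rate)
    is_case = rng.random(n) < p_event

    # regimen stratum and latency (cases only; conditional latency model)
    if set(config.latency_params) == {"all"}:
        stratum = np.array(["all"] * n)
    else:
        stratum = np.where(high_dose, REGIMEN_Q4W_120, REGIMEN_Q6M_60)
    latency = np.full(n, np.nan)
    for label, (alpha, beta) in config.latency_params.items():
        mask = exposed & is_case & (stratum == label)
        latency[mask] = alpha * rng.weibull(beta, int(mask.sum()))
    # whole days (>= 1): onset dates carry day resolution, so the recorded
    # truth must match what latency extraction can recover exactly
    latency = np.where(np.isnan(latency), np.nan, np.maximum(np.round(latency), 1.0))

    window_start, window_end = config.calendar_window
    window_days = (window_end - window_start).days
    start_offsets = rng.integers(0, window_days + 1, n)
    fda_offsets = rng.integers(30, window_days + 400, n)

    hcp = rng.random(n) < config.p_hcp
    country_idx = rng.choice(len(COUNTRIES), n, p=COUNTRY_PROBS)
    bg_drug_idx = rng.integers(0, len(BACKGROUND_DRUGS), n)
    bg_event_idx = rng.integers(0, len(BACKGROUND_EVENTS), n)
    outcome_draw = rng.random(n)

    miss = config.missing_rates
    miss_age = rng.random(n) < miss.get("age", 0.0)
    miss_sex = rng.random(n) < miss.get("sex", 0.0)
    miss_dose = rng.random(n) < miss.get("dose", 0.0)
    miss_rep = rng.random(n) < miss.get("reporter", 0.0)
    miss_tto = rng.random(n) < miss.get("tto", 0.0)

    # plain-Python views: the per-report loop is the hot path
    exposed_l = exposed.tolist()
    male_l = male.tolist()
    age65_l = age65.tolist()
    age_years_l = age_years.tolist()
    high_dose_l = high_dose.tolist()
    co_flags_l = {k: v.tolist() for k, v in co_flags.items()}
    is_case_l = is_case.tolist()
    stratum_l = stratum.tolist()
    latency_l = latency.tolist()
    start_offsets_l = start_offsets.tolist()
    fda_offsets_l = fda_offsets.tolist()
    hcp_l = hcp.tolist()
    country_idx_l = country_idx.tolist()
    bg_drug_idx_l = bg_drug_idx.tolist()
    bg_event_idx_l = bg_event_idx.tolist()
    outcome_draw_l = outcome_draw.tolist()
    miss_age_l = miss_age.tolist()
    miss_sex_l = miss_sex.tolist()
    miss_dose_l = miss_dose.tolist()
    miss_rep_l = miss_rep.tolist()
    miss_tto_l = miss_tto.tolist()
    exposed, male, age65, high_dose, is_case = (
        exposed_l, male_l, age65_l, high_dose_l, is_case_l,
    )
    age_years, stratum, latency = age_years_l, stratum_l, latency_l
    start_offsets, fda_offsets = start_offsets_l, fda_offsets_l
    hcp, country_idx = hcp_l, country_idx_l
    bg_drug_idx, bg_event_idx = bg_drug_idx_l, bg_event_idx_l
    outcome_draw = outcome_draw_l
    miss_age, miss_sex, miss_dose = miss_age_l, miss_sex_l, miss_dose_l
    miss_rep, miss_tto = miss_rep_l, miss_tto_l
    co_flags_loop = co_flags_l

    reports: list[Report] = []
    truth_rows = []
    target = config.target_drug
    for i in range(n):
        pid = 1000 + 10 * i
        therapy_start = None
        event_date = None
        if exposed[i]:
            therapy_start = window_start + dt.timedelta(days=int(start_offsets[i]))
            if is_case[i] and not np.isnan(latency[i]):
                event_date = therapy_start + dt.timedelta(days=int(latency[i]))
        drugs = []
        if exposed[i]:
            dose_text = None
            regimen = None
            if not miss_dose[i]:
                dose_text = "120 MG, Q4W" if high_dose[i] else "60 MG, Q6M"
                regimen = REGIMEN_Q4W_120 if high_dose[i] else REGIMEN_Q6M_60
            drugs.append(
                DrugEntry(
                    name_raw=target,
                    name_std=target,
                    role="PS",
                    dose_text=dose_text,
                    regimen=regimen,
                    therapy_start=None if miss_tto[i] else therapy_start,
                )
            )
            for name in co_names:
                if co_flags_loop[name][i]:
                    drugs.append(DrugEntry(name_raw=name, name_std=name, role="C"))
        else:
            bg = BACKGROUND_DRUGS[bg_drug_idx[i]]
            drugs.append(DrugEntry(name_raw=bg, name_std=bg, role="PS"))

        events = [BACKGROUND_EVENTS[bg_event_idx[i]]]
        if is_case[i]:
            events.append(config.event_pt)

        outcomes = frozenset()
        if outcome_draw[i] < 0.10:
            outcomes = frozenset({"death"})
        elif outcome_draw[i] < 0.25:
            outcomes = frozenset({"hospitalized"})
        elif outcome_draw[i] < 0.60:
            outcomes = frozenset({"other"})

        reports.append(
            Report(
                primary_id=pid,
                case_id=i,
                fda_receipt_date=window_start
                + dt.timedelta(days=int(fda_offsets[i])),
                event_date=None if miss_tto[i] else event_date,
                age_years=None if miss_age[i] else float(age_years[i]),
                sex=None if miss_sex[i] else ("male" if male[i] else "female"),
                reporter=None
                if miss_rep[i]
                else (
                    "healthcare_professional"
                    if hcp[i]
                    else "non_healthcare_professional"
                ),
                country=COUNTRIES[country_idx[i]],
                outcomes=outcomes,
                drugs=drugs,
                events=events,
            )
        )
        truth_rows.append(
            (
                pid,
                i,
                bool(exposed[i]),
                bool(male[i]),
                bool(age65[i]),
                float(age_years[i]),
                bool(high_dose[i]),
                *[bool(co_flags_loop[name][i]) for name in co_names],
                bool(is_case[i]),
                str(stratum[i]) if exposed[i] else "",
                float(latency[i]) if not np.isnan(latency[i]) else np.nan,
                bool(miss_tto[i]),
            )
        )

    canonical_ids = frozenset(r.primary_id for r in reports)

    # duplicate injection: earlier versions that dedup must discard
    dup_mask = rng.random(n) < config.duplicate_rate
    same_date = rng.random(n) < 0.3
    date_back = rng.integers(1, 300, n)
    duplicates: list[Report] = []
    for i in np.flatnonzero(dup_mask):
        canon = reports[i]
        if same_date[i]:
            dup_date = canon.fda_receipt_date  # tie: lower PRIMARYID loses
        else:
            dup_date = canon.fda_receipt_date - dt.timedelta(days=int(date_back[i]))
        duplicates.append(
            Report(
                primary_id=canon.primary_id - 1 - int(i % 5),
                case_id=canon.case_id,
                fda_receipt_date=dup_date,
                event_date=canon.event_date,
                age_years=canon.age_years,
                sex=canon.sex,
                reporter="non_healthcare_professional",
                country=canon.country,
                outcomes=canon.outcomes,
                drugs=[
                    DrugEntry(
                        d.name_raw, d.name_std, d.role, d.dose_text, d.regimen,
                        d.therapy_start,
                    )
                    for d in canon.drugs
                ],
                events=list(canon.events),
            )
        )
    all_reports = reports + duplicates
    order = rng.permutation(len(all_reports))
    all_reports = [all_reports[j] for j in order]

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "primary_id", "case_id", "exposed", "male", "age_ge_65",
            "age_years", "high_dose", *co_names, "is_case", "stratum",
            "latency_days", "tto_masked",
        ],
    )
    strata = {
        label: {
            "alpha": alpha,
            "beta": beta,
            "median_days": alpha * math.log(2) ** (1.0 / beta),
        }
        for label, (alpha, beta) in config.latency_params.items()
    }
    gt = GroundTruth(
        true_ror=_true_marginal_ror(config),
        true_or={
            k: math.exp(v) for k, v in config.true_log_or.items() if k != "intercept"
        },
        strata=strata,
        canonical_primary_ids=canonical_ids,
        report_truth=truth,
        config=config,
    )
    return all_reports, gt


# ---------------------------------------------------------------------------
# FAERS ASCII writer (inverse of faers_core.read_faers_tables)
# ---------------------------------------------------------------------------


def _fmt_date(d: dt.date | None) -> str:
    return d.strftime("%Y%m%d") if d else ""


def write_faers_tables(
    reports: Sequence[Report], out_dir: str | Path, sep: str = "|"
) -> dict[str, Path]:
    """Emit DEMO/DRUG/REAC/THER/OUTC files in the FAERS ASCII dialect.

    The output round-trips through ``read_faers_tables`` field-equal
    (names written are standardized, so an empty synonym map suffices).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    demo_lines = [sep.join(
        ["primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
         "sex", "occp_cod", "reporter_country"])]
    drug_lines = [sep.join(
        ["primaryid", "drug_seq", "role_cod", "drugname", "dose_vbm"])]
    reac_lines = [sep.join(["primaryid", "pt"])]
    ther_lines = [sep.join(["primaryid", "dsg_drug_seq", "start_dt"])]
    outc_lines = [sep.join(["primaryid", "outc_cod"])]
    sex_code = {"male": "M", "female": "F", None: ""}
    rep_code = {
        "healthcare_professional": "MD",
        "non_healthcare_professional": "CN",
        None: "",
    }
    outc_code = {v: k for k, v in
                 {"DE": "death", "HO": "hospitalized", "LT": "life_threatening",
                  "DS": "disability", "RI": "required_intervention",
                  "OT": "other"}.items()}
    for r in reports:
        demo_lines.append(sep.join([
            str(r.primary_id), str(r.case_id), _fmt_date(r.fda_receipt_date),
            _fmt_date(r.event_date),
            "" if r.age_years is None else repr(float(r.age_years)), "YR",
            sex_code[r.sex], rep_code[r.reporter], r.country or "",
        ]))
        for seq, d in enumerate(r.drugs, start=1):
            drug_lines.append(sep.join([
                str(r.primary_id), str(seq), d.role, d.name_raw,
                d.dose_text or "",
            ]))
            if d.therapy_start is not None:
                ther_lines.append(sep.join([
                    str(r.primary_id), str(seq), _fmt_date(d.therapy_start)]))
        for pt in r.events:
            reac_lines.append(sep.join([str(r.primary_id), pt]))
        for o in sorted(r.outcomes):
            outc_lines.append(sep.join([str(r.primary_id), outc_code[o]]))

    paths = {}
    for name, lines in [
        ("demo", demo_lines), ("drug", drug_lines), ("reac", reac_lines),
        ("ther", ther_lines), ("outc", outc_lines),
    ]:
        p = out / f"{name}.txt"
        p.write_text("\n".join(lines) + "\n")
        paths[name] = p
    return paths
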
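"""Core data model for FAERS-style spontaneous adverse-event reports.

FAERS (the FDA Adverse Event Reporting System) distributes quarterly ASCII
extracts as delimited tables: DEMO (one row per report version), DRUG,
REAC, THER and OUTC (child tables joined on PRIMARYID).  This module
provides the in-memory report model, a reader for that dialect, the
version-deduplication rule used in pharmacovigilance practice (keep the
most recent FDA receipt date per CASEID, break ties on the higher
PRIMARYID), and the exposure/case classification rules that underlie
case/non-case disproportionality analysis.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("faerspv")

# ---------------------------------------------------------------------------
# Constants shared across the package
# ---------------------------------------------------------------------------

ROLE_CODES = ("PS", "SS", "C", "I")

REGIMEN_Q6M_60 = "q6m_60mg"
REGIMEN_Q4W_120 = "q4w_120mg"
REGIMEN_OTHER = "other"

OUTCOME_CODES = {
    "DE": "death",
    "HO": "hospitalized",
    "LT": "life_threatening",
    "DS": "disability",
    "RI": "required_intervention",
    "OT": "other",
}

# FAERS OCCP_COD values: MD physician, PH pharmacist, OT other health
# professional, HP health professional, CN consumer, LW lawyer.
_HCP_CODES = {"MD", "PH", "OT", "HP"}
_NON_HCP_CODES = {"CN", "LW"}

_AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
}
MAX_PLAUSIBLE_AGE = 130.0

_RE_120 = re.compile(r"120\s*mg", re.IGNORECASE)
_RE_60 = re.compile(r"60\s*mg", re.IGNORECASE)

CLASS_EXPOSED_CASE = "exposed_case"
CLASS_EXPOSED_NONCASE = "exposed_noncase"
CLASS_UNEXPOSED_CASE = "unexposed_case"
CLASS_UNEXPOSED_NONCASE = "unexposed_noncase"
CLASS_NOT_CLASSIFIABLE = "not_classifiable"
CLASSES = (
    CLASS_EXPOSED_CASE,
    CLASS_EXPOSED_NONCASE,
    CLASS_UNEXPOSED_CASE,
    CLASS_UNEXPOSED_NONCASE,
    CLASS_NOT_CLASSIFIABLE,
)


def normalize_name(name: str) -> str:
    """Case/whitespace normalization applied to drug names and event PTs."""
    return " ".join(name.split()).casefold()


def parse_regimen(dose_text: str | None) -> str | None:
    """Map a verbatim dose/regimen string onto the 60 mg Q6m vs 120 mg Q4w
    dichotomy.

    ``120 mg`` anywhere in the text maps to the oncology regimen, ``60 mg``
    to the osteoporosis regimen; text matching both or neither is ``other``;
    absent text is missing (``None``).
    """
    if dose_text is None or not dose_text.strip():
        return None
    has120 = bool(_RE_120.search(dose_text))
    has60 = bool(_RE_60.search(dose_text))
    if has120 and not has60:
        return REGIMEN_Q4W_120
    if has60 and not has120:
        return REGIMEN_Q6M_60
    return REGIMEN_OTHER


def harmonize_age(age: float | str | None, unit: str | None) -> float | None:
    """Convert a FAERS AGE + AGE_COD pair to years.

    Units YR/DEC/MON/WK/DY are handled; unknown units, unparseable values,
    negative ages and ages above 130 years become missing.
    """
    if age is None:
        return None
    try:
        value = float(age)
    except (TypeError, ValueError):
        return None
    factor = _AGE_UNIT_TO_YEARS.get((unit or "YR").strip().upper())
    if factor is None:
        return None
    years = value * factor
    if years < 0 or years > MAX_PLAUSIBLE_AGE:
        return None
    return years


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(slots=True)
class DrugEntry:
    """One drug row of a report.

    ``name_std`` is the standardized generic name obtained from the
    user-supplied synonym map; ``regimen`` is derived deterministically
    from ``dose_text`` by :func:`parse_regimen`.
    """

    name_raw: str
    name_std: str
    role: str
    dose_text: str | None = None
    regimen: str | None = None
    therapy_start: dt.date | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLE_CODES:
            raise ValueError(f"unknown FAERS role code {self.role!r}")


@dataclass(slots=True)
class Report:
    """One (deduplicated) safety report."""

    primary_id: int
    case_id: int
    fda_receipt_date: dt.date
    event_date: dt.date | None = None  # DEMO EVENT_DT, onset of the reaction
    age_years: float | None = None
    sex: str | None = None  # "male" / "female" / None
    reporter: str | None = None  # "healthcare_professional" / "non_..." / None
    country: str | None = None
    outcomes: frozenset[str] = field(default_factory=frozenset)
    drugs: list[DrugEntry] = field(default_factory=list)
    events: list[str] = field(default_factory=list)

    def has_event(self, event: "EventLabel") -> bool:
        return any(event.matches(pt) for pt in self.events)

    def drug_names_std(self) -> set[str]:
        return {normalize_name(d.name_std) for d in self.drugs}


@dataclass(frozen=True, slots=True)
class EventLabel:
    """A MedDRA preferred term treated as an opaque label.

    Comparison is case-insensitive on normalized whitespace; the numeric
    PT code participates only when both sides carry one.
    """

    pt_name: str
    pt_code: int | None = None

    def __post_init__(self) -> None:
        if not self.pt_name.strip():
            raise ValueError("pt_name must be non-empty")

    def matches(self, pt: "str | EventLabel") -> bool:
        if isinstance(pt, EventLabel):
            if self.pt_code is not None and pt.pt_code is not None:
                return self.pt_code == pt.pt_code
            return normalize_name(self.pt_name) == normalize_name(pt.pt_name)
        return normalize_name(self.pt_name) == normalize_name(pt)


@dataclass(frozen=True, slots=True)
class ExposureSpec:
    """Definition of an exposure for the case/non-case design.

    A report is *exposed* when the target drug appears with the required
    role, every co-drug appears in any role, and the optional regimen /
    demographic filters pass.  Reports where a filter references a missing
    field are *not classifiable* for this exposure and are excluded from
    the corresponding table only.
    """

    target_drug: str
    required_role: str = "PS"  # "PS" or "any"
    co_drugs: frozenset[str] = frozenset()
    regimen_filter: str | None = None
    sex: str | None = None
    age_min: float | None = None
    age_max: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.target_drug.strip():
            raise ValueError("target_drug must be non-empty")
        if self.required_role not in ("PS", "any"):
            raise ValueError("required_role must be 'PS' or 'any'")

    def describe(self) -> str:
        if self.label:
            return self.label
        parts = [self.target_drug, self.required_role]
        if self.co_drugs:
            parts.append("+" + "+".join(sorted(self.co_drugs)))
        if self.regimen_filter:
            parts.append(self.regimen_filter)
        if self.sex:
            parts.append(self.sex)
        if self.age_min is not None or self.age_max is not None:
            parts.append(f"age[{self.age_min},{self.age_max})")
        return "|".join(parts)

    def refine(self, **changes) -> "ExposureSpec":
        """Return a copy with stratum filters added (used for Figure-2 style
        stratified analyses)."""
        return replace(self, **changes)


def classify_report(report: Report, exposure: ExposureSpec, event: EventLabel) -> str:
    """Assign a report to one cell of the case/non-case 2x2 design.

    Drug-membership checks short-circuit first: a report that lacks the
    target drug (or a required co-drug) is unexposed regardless of any
    demographic filter, so missing demographics never make the comparator
    unclassifiable.  Only when the drug criteria pass and a regimen or
    demographic filter references a missing field is the report flagged
    ``not_classifiable``.
    """
    is_case = report.has_event(event)
    target = normalize_name(exposure.target_drug)

    target_entries = [
        d
        for d in report.drugs
        if normalize_name(d.name_std) == target
        and (exposure.required_role == "any" or d.role == exposure.required_role)
    ]
    exposed = bool(target_entries)
    if exposed and exposure.co_drugs:
        present = report.drug_names_std()
        exposed = all(normalize_name(cd) in present for cd in exposure.co_drugs)

    if exposed and exposure.regimen_filter is not None:
        regimens = {d.regimen for d in target_entries}
        known = regimens - {None}
        if not known:
            return CLASS_NOT_CLASSIFIABLE
        exposed = exposure.regimen_filter in known
    if exposed and exposure.sex is not None:
        if report.sex is None:
            return CLASS_NOT_CLASSIFIABLE
        exposed = report.sex == exposure.sex
    if exposed and (exposure.age_min is not None or exposure.age_max is not None):
        if report.age_years is None:
            return CLASS_NOT_CLASSIFIABLE
        lo = exposure.age_min if exposure.age_min is not None else float("-inf")
        hi = exposure.age_max if exposure.age_max is not None else float("inf")
        exposed = lo <= report.age_years < hi

    if exposed:
        return CLASS_EXPOSED_CASE if is_case else CLASS_EXPOSED_NONCASE
    return CLASS_UNEXPOSED_CASE if is_case else CLASS_UNEXPOSED_NONCASE


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------


def deduplicate(reports: Sequence[Report]) -> list[Report]:
    """Collapse report versions to one survivor per CASEID.

    The survivor maximizes ``(fda_receipt_date, primary_id)``
    lexicographically: the most recent FDA receipt date wins, and the
    higher PRIMARYID breaks exact date ties.  Output is sorted by case_id
    for determinism.  Two reports sharing a primary_id violate the FAERS
    identifier contract and raise.
    """
    seen_primary: set[int] = set()
    best: dict[int, Report] = {}
    for r in reports:
        if r.primary_id in seen_primary:
            raise ValueError(f"duplicate primary_id {r.primary_id}")
        seen_primary.add(r.primary_id)
        cur = best.get(r.case_id)
        if cur is None or (r.fda_receipt_date, r.primary_id) > (
            cur.fda_receipt_date,
            cur.primary_id,
        ):
            best[r.case_id] = r
    return [best[cid] for cid in sorted(best)]


# ---------------------------------------------------------------------------
# FAERS ASCII dialect reader
# ---------------------------------------------------------------------------

DEMO_COLUMNS = [
    "primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod", "sex",
    "occp_cod", "reporter_country",
]
DRUG_COLUMNS = ["primaryid", "drug_seq", "role_cod", "drugname", "dose_vbm"]
REAC_COLUMNS = ["primaryid", "pt"]
THER_COLUMNS = ["primaryid", "dsg_drug_seq", "start_dt"]
OUTC_COLUMNS = ["primaryid", "outc_cod"]


@dataclass(slots=True)
class LoadReport:
    """Tallies from one read of a FAERS table set."""

    n_demo: int = 0
    n_drug: int = 0
    n_reac: int = 0
    n_ther: int = 0
    n_outc: int = 0
    orphans: dict = field(default_factory=dict)  # table -> orphan row count
    malformed: dict = field(default_factory=dict)  # table -> skipped row count

    def total_orphans(self) -> int:
        return sum(self.orphans.values())


def load_synonym_map(path: str | Path, sep: str | None = None) -> dict[str, str]:
    """Read a two-column raw->standard drug-name map (tab or '|' delimited)."""
    mapping: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        use_sep = sep or ("\t" if "\t" in line else "|")
        parts = line.split(use_sep)
        if len(parts) < 2:
            continue
        mapping[normalize_name(parts[0])] = parts[1].strip()
    return mapping


def standardize_drug_name(raw: str, synonym_map: Mapping[str, str]) -> str:
    return synonym_map.get(normalize_name(raw), raw.strip())


def _sniff_sep(path: Path) -> str:
    header = path.open("r", encoding="utf-8", errors="replace").readline()
    return "$" if header.count("$") > header.count("|") else "|"


def _read_table(path: Path) -> pd.DataFrame:
    sep = _sniff_sep(path)
    df = pd.read_csv(
        path, sep=sep, dtype=str, keep_default_na=False, engine="python"
    )
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def parse_faers_date(text: str | None) -> dt.date | None:
    """Parse a YYYYMMDD FAERS date; partial (YYYYMM / YYYY) or malformed
    dates become missing."""
    if not text:
        return None
    text = text.strip()
    if len(text) != 8 or not text.isdigit():
        return None
    try:
        return dt.date(int(text[:4]), int(text[4:6]), int(text[6:8]))
    except ValueError:
        return None


def _parse_sex(code: str) -> str | None:
    code = code.strip().upper()
    if code == "M":
        return "male"
    if code == "F":
        return "female"
    return None


def _parse_reporter(code: str) -> str | None:
    code = code.strip().upper()
    if code in _HCP_CODES:
        return "healthcare_professional"
    if code in _NON_HCP_CODES:
        return "non_healthcare_professional"
    return None


def read_faers_tables(
    paths: Mapping[str, str | Path],
    synonym_map: Mapping[str, str] | None = None,
) -> tuple[list[Report], LoadReport]:
    """Read FAERS ASCII quarterly tables into Report objects.

    ``paths`` maps table names (``demo`` required; ``drug``, ``reac``,
    ``ther``, ``outc`` optional) to file locations.  The delimiter ('|' or
    '$') is auto-detected per file from the header row.  Child rows whose
    primaryid has no DEMO parent are dropped and counted as orphans;
    malformed rows are logged, skipped and counted.
    """
    synonym_map = synonym_map or {}
    if "demo" not in paths:
        raise FileNotFoundError("DEMO table is required")
    demo = _read_table(Path(paths["demo"]))
    load = LoadReport(n_demo=len(demo))

    reports: dict[int, Report] = {}
    for _, row in demo.iterrows():
        try:
            pid = int(row["primaryid"])
            cid = int(row["caseid"])
        except (KeyError, ValueError):
            load.malformed["demo"] = load.malformed.get("demo", 0) + 1
            logger.warning("skipping malformed DEMO row: %s", dict(row))
            continue
        fda_dt = parse_faers_date(row.get("fda_dt"))
        if fda_dt is None:
            # a report version without a receipt date cannot enter dedup
            load.malformed["demo"] = load.malformed.get("demo", 0) + 1
            logger.warning("skipping DEMO row %s with unparseable FDA_DT", pid)
            continue
        if pid in reports:
            raise ValueError(f"duplicate primaryid {pid} in DEMO")
        reports[pid] = Report(
            primary_id=pid,
            case_id=cid,
            fda_receipt_date=fda_dt,
            event_date=parse_faers_date(row.get("event_dt")),
            age_years=harmonize_age(row.get("age") or None, row.get("age_cod")),
            sex=_parse_sex(row.get("sex", "")),
            reporter=_parse_reporter(row.get("occp_cod", "")),
            country=(row.get("reporter_country") or "").strip() or None,
        )

    drug_index: dict[tuple[int, int], DrugEntry] = {}
    if "drug" in paths:
        drug = _read_table(Path(paths["drug"]))
        load.n_drug = len(drug)
        for _, row in drug.iterrows():
            try:
                pid = int(row["primaryid"])
                seq = int(row.get("drug_seq") or 0)
                role = row["role_cod"].strip().upper()
                entry = DrugEntry(
                    name_raw=row["drugname"],
                    name_std=standardize_drug_name(row["drugname"], synonym_map),
                    role=role,
                    dose_text=(row.get("dose_vbm") or "").strip() or None,
                )
            except (KeyError, ValueError):
                load.malformed["drug"] = load.malformed.get("drug", 0) + 1
                continue
            entry.regimen = parse_regimen(entry.dose_text)
            if pid not in reports:
                load.orphans["drug"] = load.orphans.get("drug", 0) + 1
                continue
            reports[pid].drugs.append(entry)
            drug_index[(pid, seq)] = entry

    if "reac" in paths:
        reac = _read_table(Path(paths["reac"]))
        load.n_reac = len(reac)
        for _, row in reac.iterrows():
            try:
                pid = int(row["primaryid"])
                pt = row["pt"].strip()
            except (KeyError, ValueError):
                load.malformed["reac"] = load.malformed.get("reac", 0) + 1
                continue
            if pid not in reports:
                load.orphans["reac"] = load.orphans.get("reac", 0) + 1
                continue
            if pt:
                reports[pid].events.append(pt)

    if "ther" in paths:
        ther = _read_table(Path(paths["ther"]))
        load.n_ther = len(ther)
        for _, row in ther.iterrows():
            try:
                pid = int(row["primaryid"])
                seq = int(row.get("dsg_drug_seq") or 0)
            except (KeyError, ValueError):
                load.malformed["ther"] = load.malformed.get("ther", 0) + 1
                continue
            if pid not in reports:
                load.orphans["ther"] = load.orphans.get("ther", 0) + 1
                continue
            entry = drug_index.get((pid, seq))
            if entry is not None:
                entry.therapy_start = parse_faers_date(row.get("start_dt"))

    if "outc" in paths:
        outc = _read_table(Path(paths["outc"]))
        load.n_outc = len(outc)
        for _, row in outc.iterrows():
            try:
                pid = int(row["primaryid"])
                code = row["outc_cod"].strip().upper()
            except (KeyError, ValueError):
                load.malformed["outc"] = load.malformed.get("outc", 0) + 1
                continue
            if pid not in reports:
                load.orphans["outc"] = load.orphans.get("outc", 0) + 1
                continue
            name = OUTCOME_CODES.get(code)
            if name:
                reports[pid].outcomes = reports[pid].outcomes | {name}

    out = [reports[pid] for pid in sorted(reports)]
    return out, load
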
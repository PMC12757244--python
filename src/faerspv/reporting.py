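"""Descriptive summaries and the end-to-end pipeline.

``describe_cohort`` produces the baseline-characteristics table of a
case/non-case cohort (reporter type, sex, age bands, top countries,
outcomes) with per-variable "data available" denominators: percentages
are computed within the reports where the variable is observed, never
over the whole cohort.

``run_pipeline`` orchestrates clean -> describe -> disproportionality ->
regression -> time-to-onset from a single configuration (real FAERS
tables or the synthetic generator), writes delimited outputs, and emits
a machine-readable manifest with the counts at every stage.  All stages
are computed before anything is written, so a failing stage leaves no
partial output; runs are byte-deterministic for fixed inputs and seeds.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import dispro, regression, tto
from .faers_core import (
    REGIMEN_Q4W_120,
    REGIMEN_Q6M_60,
    CLASS_EXPOSED_CASE,
    CLASS_EXPOSED_NONCASE,
    EventLabel,
    ExposureSpec,
    Report,
    classify_report,
    deduplicate,
    load_synonym_map,
    normalize_name,
    read_faers_tables,
)
from .synth import GroundTruth, SynthConfig, generate, write_faers_tables

logger = logging.getLogger("faerspv")

AGE_BANDS = ((0.0, 18.0, "0-17"), (18.0, 45.0, "18-44"),
             (45.0, 65.0, "45-64"), (65.0, float("inf"), ">=65"))


class PipelineError(RuntimeError):
    """A stage-labeled fatal pipeline error."""


def share(count: float, total: float, ndigits: int | None = 2) -> float:
    """Percentage of ``count`` within ``total`` (the "data available"
    denominator convention used throughout the descriptive tables)."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = 100.0 * count / total
    return pct if ndigits is None else round(pct, ndigits)


def _summarize_group(reports: Sequence[Report]) -> dict:
    n = len(reports)
    out: dict = {"n": n}

    rep_known = [r for r in reports if r.reporter is not None]
    out["reporter"] = {"data_available": len(rep_known)}
    for key in ("healthcare_professional", "non_healthcare_professional"):
        k = sum(1 for r in rep_known if r.reporter == key)
        out["reporter"][key] = {
            "n": k,
            "pct": share(k, len(rep_known)) if rep_known else None,
        }

    sex_known = [r for r in reports if r.sex is not None]
    out["sex"] = {"data_available": len(sex_known)}
    for key in ("male", "female"):
        k = sum(1 for r in sex_known if r.sex == key)
        out["sex"][key] = {
            "n": k,
            "pct": share(k, len(sex_known)) if sex_known else None,
        }

    ages = np.array([r.age_years for r in reports if r.age_years is not None])
    out["age"] = {"data_available": len(ages)}
    for lo, hi, label in AGE_BANDS:
        k = int(np.sum((ages >= lo) & (ages < hi))) if len(ages) else 0
        out["age"][label] = {
            "n": k,
            "pct": share(k, len(ages)) if len(ages) else None,
        }
    if len(ages):
        q25, med, q75 = np.percentile(ages, [25, 50, 75])
        out["age"]["median"] = round(float(med), 1)
        out["age"]["iqr"] = [round(float(q25), 1), round(float(q75), 1)]

    countries = pd.Series(
        [r.country for r in reports if r.country], dtype="object"
    )
    out["countries_top3"] = [
        {"country": c, "n": int(k), "pct": share(int(k), len(countries))}
        for c, k in countries.value_counts().head(3).items()
    ] if len(countries) else []

    with_outcome = [r for r in reports if r.outcomes]
    out["outcome"] = {"data_available": len(with_outcome)}
    for key in ("death", "hospitalized", "life_threatening", "disability",
                "required_intervention", "other"):
        k = sum(1 for r in with_outcome if key in r.outcomes)
        out["outcome"][key] = {
            "n": k,
            "pct": share(k, len(with_outcome)) if with_outcome else None,
        }
    return out


def describe_cohort(
    reports: Sequence[Report], cohort: ExposureSpec, event: EventLabel
) -> dict:
    """Baseline-characteristics summary of the cohort, split case/non-case."""
    cases, noncases = [], []
    for r in reports:
        cls = classify_report(r, cohort, event)
        if cls == CLASS_EXPOSED_CASE:
            cases.append(r)
        elif cls == CLASS_EXPOSED_NONCASE:
            noncases.append(r)
    return {
        "all": _summarize_group(cases + noncases),
        "case": _summarize_group(cases),
        "noncase": _summarize_group(noncases),
    }


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Single configuration driving the whole pipeline.

    Exactly one input mode: ``synth`` (keyword overrides for
    :class:`SynthConfig`) or ``tables`` (paths to FAERS ASCII files).
    """

    out_dir: str = "faerspv_out"
    seed: int = 0
    synth: dict | None = None
    tables: dict | None = None
    synonym_map: str | None = None
    target_drug: str = "denosumab"
    event_pt: str = "Osteonecrosis of jaw"
    event_pt_code: int | None = 10064658
    co_drugs: tuple = ("zoledronic acid", "prednisolone")
    screen_alpha: float = 0.20
    force_include: tuple = ("age_ge_65",)
    tto_anchor: str = "target"
    write_tables: bool = False
    make_plots: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.synth is None) == (self.tables is None):
            raise ValueError("exactly one of synth/tables must be given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        if "co_drugs" in data:
            data["co_drugs"] = tuple(data["co_drugs"])
        if "force_include" in data:
            data["force_include"] = tuple(data["force_include"])
        return cls(**data)


def _validate_drug_names(config: RunConfig, synth_cfg: SynthConfig | None,
                         synonym_map: Mapping[str, str] | None) -> None:
    names = [config.target_drug, *config.co_drugs]
    if synth_cfg is not None:
        known = {normalize_name(synth_cfg.target_drug)} | {
            normalize_name(k) for k in synth_cfg.co_drug_probs
        }
        unknown = [n for n in names if normalize_name(n) not in known]
    elif synonym_map:
        std = {normalize_name(v) for v in synonym_map.values()}
        unknown = [n for n in names if normalize_name(n) not in std]
    else:
        unknown = []
    if unknown:
        raise PipelineError(f"[validate] unknown drug name(s): {unknown}")


def _tto_rows(
    reports: Sequence[Report],
    base: ExposureSpec,
    event: EventLabel,
    co_drugs: Sequence[str],
    anchor: str,
) -> tuple[pd.DataFrame, dict]:
    """Table-3-shaped strata: overall, each regimen, each co-drug combo.

    Each subgroup's Mann-Whitney p compares it with its complement among
    exposed cases (the other regimen; cases without that co-drug).
    """
    rows = []
    samples = {}

    def fit_fields(sample):
        if sample.n >= tto.MIN_SAMPLE and np.ptp(sample.values) > 0:
            f = tto.weibull_fit(sample)
            return {
                "alpha": f.alpha, "alpha_ci_low": f.alpha_ci[0],
                "alpha_ci_high": f.alpha_ci[1], "beta": f.beta,
                "beta_ci_low": f.beta_ci[0], "beta_ci_high": f.beta_ci[1],
                "pattern": f.pattern,
            }
        return {k: np.nan for k in (
            "alpha", "alpha_ci_low", "alpha_ci_high", "beta",
            "beta_ci_low", "beta_ci_high")} | {"pattern": ""}

    def add_row(label, sample, complement=None):
        samples[label] = sample
        row = {"stratum": label, "n": sample.n}
        if sample.n:
            q25, med, q75 = np.percentile(sample.values, [25, 50, 75])
            row |= {"median_days": float(med), "q25": float(q25),
                    "q75": float(q75)}
        else:
            row |= {"median_days": np.nan, "q25": np.nan, "q75": np.nan}
        row["mann_whitney_p"] = (
            tto.mann_whitney(sample.values, complement.values)
            if complement is not None and sample.n and complement.n
            else np.nan
        )
        row |= fit_fields(sample)
        rows.append(row)

    overall = tto.extract_latencies(reports, base, event, anchor=anchor,
                                    label="overall")
    add_row("overall", overall)

    for reg, other in ((REGIMEN_Q6M_60, REGIMEN_Q4W_120),
                       (REGIMEN_Q4W_120, REGIMEN_Q6M_60)):
        s = tto.extract_latencies(
            reports, base.refine(regimen_filter=reg), event, anchor=anchor,
            label=reg)
        comp = tto.extract_latencies(
            reports, base.refine(regimen_filter=other), event, anchor=anchor)
        add_row(reg, s, comp)

    for cd in co_drugs:
        cd_norm = normalize_name(cd)
        has_cd = lambda r, _n=cd_norm: _n in r.drug_names_std()  # noqa: E731
        s = tto.extract_latencies(
            reports, base.refine(co_drugs=frozenset({cd})), event,
            anchor=anchor, label=f"with_{cd}")
        comp = tto.extract_latencies(
            reports, base, event, anchor=anchor,
            where=lambda r: not has_cd(r))
        add_row(f"with_{cd}", s, comp)

    return pd.DataFrame(rows), {k: v.n for k, v in samples.items()}


def run_pipeline(
    config: RunConfig,
) -> dict:
    """Execute all stages and write the output bundle.

    Returns the manifest (also written as ``manifest.json``).  Outputs:
    ``describe.json``, ``dispro.csv``, ``forest.csv``, ``regression.csv``,
    ``tto.csv`` and optionally the synthetic tables and histograms.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    event = EventLabel(config.event_pt, config.event_pt_code)
    base = ExposureSpec(target_drug=config.target_drug, required_role="PS",
                        label="overall")

    # --- stage: load -------------------------------------------------------
    synth_cfg = None
    ground_truth: GroundTruth | None = None
    try:
        if config.synth is not None:
            synth_cfg = SynthConfig(**{"seed": config.seed, **config.synth})
            _validate_drug_names(config, synth_cfg, None)
            raw_reports, ground_truth = generate(synth_cfg)
            load_info = {"mode": "synthetic", "n_raw": len(raw_reports)}
        else:
            synonym_map = (
                load_synonym_map(config.synonym_map)
                if config.synonym_map
                else {}
            )
            _validate_drug_names(config, None, synonym_map)
            raw_reports, load = read_faers_tables(config.tables, synonym_map)
            load_info = {
                "mode": "real",
                "n_raw": len(raw_reports),
                "orphans": load.orphans,
                "malformed": load.malformed,
            }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"[load] {exc}") from exc
    logger.info("load: %d raw reports", len(raw_reports))

    # --- stage: clean ------------------------------------------------------
    try:
        reports = deduplicate(raw_reports)
    except Exception as exc:
        raise PipelineError(f"[clean] {exc}") from exc
    logger.info("clean: %d deduplicated reports", len(reports))

    # --- stage: describe ---------------------------------------------------
    try:
        description = describe_cohort(reports, base, event)
    except Exception as exc:
        raise PipelineError(f"[describe] {exc}") from exc

    # --- stage: dispro -----------------------------------------------------
    try:
        strata = dispro.default_strata(base) + [
            base.refine(co_drugs=frozenset({cd}), label=f"with_{cd}")
            for cd in config.co_drugs
        ]
        results = [dispro.analyze_exposure(reports, base, event)]
        results += dispro.stratified_rors(reports, base, event, strata)
        dispro_frame = dispro.results_to_frame(results)
    except Exception as exc:
        raise PipelineError(f"[dispro] {exc}") from exc
    logger.info("dispro: %d exposures analyzed", len(results))

    # --- stage: regression -------------------------------------------------
    try:
        cov_spec = regression.CovariateSpec(co_drugs=tuple(config.co_drugs))
        frame, tally = regression.build_frame(reports, base, event, cov_spec)
        logistic = regression.logistic_table(
            frame,
            alpha_screen=config.screen_alpha,
            force_include=frozenset(config.force_include),
        )
        regression_frame = logistic.to_frame()
    except regression.UnfittableError as exc:
        raise PipelineError(f"[regression] {exc}") from exc
    except Exception as exc:
        raise PipelineError(f"[regression] {exc}") from exc
    logger.info("regression: n=%d (%d cases)", logistic.n, logistic.n_cases)

    # --- stage: tto --------------------------------------------------------
    try:
        tto_frame, tto_counts = _tto_rows(
            reports, base, event, config.co_drugs, config.tto_anchor
        )
    except Exception as exc:
        raise PipelineError(f"[tto] {exc}") from exc
    logger.info("tto: %d strata", len(tto_frame))

    # --- write bundle (only after every stage succeeded) -------------------
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "seed": config.seed,
        "stages": {
            "load": load_info,
            "clean": {
                "n_raw": len(raw_reports),
                "n_dedup": len(reports),
                "n_removed": len(raw_reports) - len(reports),
            },
            "describe": {
                "cohort_n": description["all"]["n"],
                "cases": description["case"]["n"],
                "noncases": description["noncase"]["n"],
            },
            "dispro": {"n_exposures": len(results)},
            "regression": {
                "n": logistic.n,
                "n_cases": logistic.n_cases,
                "exclusions": tally,
                "included": list(logistic.included),
            },
            "tto": {"samples": tto_counts},
        },
    }
    if ground_truth is not None:
        manifest["ground_truth"] = {
            "true_ror": ground_truth.true_ror,
            "true_or": ground_truth.true_or,
            "strata": ground_truth.strata,
        }
    (out / "describe.json").write_text(
        json.dumps(description, indent=2, sort_keys=True) + "\n"
    )
    dispro_frame.to_csv(out / "dispro.csv", index=False, float_format="%.6g")
    dispro.write_forest_file(results, out / "forest.csv")
    regression_frame.to_csv(out / "regression.csv", index=False,
                            float_format="%.6g")
    tto_frame.to_csv(out / "tto.csv", index=False, float_format="%.6g")
    if config.write_tables and config.synth is not None:
        write_faers_tables(raw_reports, out / "tables")
    if config.make_plots:
        _plot_tto(reports, base, event, config, out)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def _plot_tto(reports, base, event, config, out: Path) -> None:
    """Histogram with fitted Weibull density per regimen stratum, plus a
    box-plot data file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy import stats as sps

    box_rows = []
    for label, spec in [
        ("overall", base),
        (REGIMEN_Q6M_60, base.refine(regimen_filter=REGIMEN_Q6M_60)),
        (REGIMEN_Q4W_120, base.refine(regimen_filter=REGIMEN_Q4W_120)),
    ]:
        sample = tto.extract_latencies(reports, spec, event,
                                       anchor=config.tto_anchor, label=label)
        box_rows += [{"stratum": label, "latency_days": v}
                     for v in sample.values]
        if sample.n < tto.MIN_SAMPLE:
            continue
        fit = tto.weibull_fit(sample)
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.hist(sample.values, bins=30, density=True, alpha=0.6)
        x = np.linspace(1, sample.values.max(), 300)
        ax.plot(x, sps.weibull_min.pdf(x, fit.beta, scale=fit.alpha))
        ax.set_xlabel("days to onset")
        ax.set_title(f"{label}: alpha={fit.alpha:.0f}, beta={fit.beta:.2f}")
        fig.tight_layout()
        fig.savefig(out / f"tto_hist_{label}.png", dpi=120)
        plt.close(fig)
    pd.DataFrame(box_rows).to_csv(out / "tto_boxplot_data.csv", index=False)
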
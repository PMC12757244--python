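import datetime as dt
import math

import pytest

import faerspv as f


@pytest.fixture(scope="session")
def event():
    return f.EventLabel("Osteonecrosis of jaw", 10064658)


@pytest.fixture(scope="session")
def base_exposure():
    return f.ExposureSpec("denosumab", required_role="PS", label="overall")


def desk_config(**overrides) -> f.SynthConfig:
    """Desk-scale study conditions: exposure and event rates large enough
    that a few thousand reports yield non-degenerate 2x2 tables."""
    params = dict(
        n_reports=5_000,
        seed=0,
        target_exposure_prob=0.10,
        background_event_rate=0.02,
        co_drug_probs={"zoledronic acid": 0.05},
        true_log_or={
            "intercept": -2.5,
            "male": math.log(3.0),
            "age_ge_65": math.log(1.5),
            "high_dose": math.log(7.0),
            "zoledronic acid": math.log(10.0),
        },
        missing_rates={"age": 0.2, "sex": 0.1, "dose": 0.2,
                       "reporter": 0.01, "tto": 0.3},
        duplicate_rate=0.1,
    )
    params.update(overrides)
    return f.SynthConfig(**params)


def null_config(**overrides) -> f.SynthConfig:
    """Planted ROR exactly 1: exposed event probability equals the
    background rate and every covariate effect is zero."""
    p0 = overrides.pop("background_event_rate", 0.02)
    params = dict(
        background_event_rate=p0,
        true_log_or={"intercept": math.log(p0 / (1 - p0))},
        co_drug_probs={},
        missing_rates={"age": 0, "sex": 0, "dose": 0, "reporter": 0, "tto": 1.0},
        duplicate_rate=0.0,
        target_exposure_prob=0.10,
    )
    params.update(overrides)
    return desk_config(**params)


@pytest.fixture(scope="session")
def synth_dataset():
    """One shared deduplicated desk-scale dataset with its ground truth."""
    reports, gt = f.generate(desk_config(n_reports=6_000, seed=42))
    return f.deduplicate(reports), gt


def make_report(pid, cid, fda, drugs=(), events=(), **kw):
    """Minimal hand-built report for rule-level tests."""
    return f.Report(
        primary_id=pid,
        case_id=cid,
        fda_receipt_date=fda if isinstance(fda, dt.date) else dt.date(*fda),
        drugs=list(drugs),
        events=list(events),
        **kw,
    )
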
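"""Time-to-onset analysis with the Weibull shape-parameter (WSP) test.

Latency is the interval in days from the initiation of the target-drug
therapy to the onset of the target event, available only for exposed
cases carrying both dates.  The latency sample is summarized by its
median and interquartile range and fitted with a two-parameter Weibull
distribution (scale alpha in days, shape beta) by maximum likelihood,
with no censoring model: reports without an onset contribute nothing,
exactly as in spontaneous-report practice, which is an acknowledged
source of bias rather than something this module corrects.

The hazard trend is read off the shape parameter: beta with a 95% CI
entirely below 1 means a decreasing hazard (early failure), a CI
containing 1 a constant hazard (random failure), and a CI entirely
above 1 an increasing hazard (wear-out failure, i.e. cumulative
toxicity).  Subgroup latencies are compared with the Mann-Whitney U
test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .faers_core import (
    CLASS_EXPOSED_CASE,
    EventLabel,
    ExposureSpec,
    Report,
    classify_report,
    normalize_name,
)

Z_95 = 1.96
MIN_SAMPLE = 10

PATTERN_EARLY = "early_failure"
PATTERN_RANDOM = "random_failure"
PATTERN_WEAR_OUT = "wear_out_failure"


class SmallSampleError(ValueError):
    """Raised when a latency sample is too small for a stable Weibull fit."""


@dataclass
class LatencySample:
    """Positive latencies (days) for one stratum, with exclusion tallies."""

    label: str
    values: np.ndarray
    n_excluded: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) and self.values.min() <= 0:
            raise ValueError("latencies must be strictly positive")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class WeibullFit:
    """Maximum-likelihood Weibull fit and its hazard-trend classification."""

    alpha: float  # scale, days
    beta: float  # shape, dimensionless
    alpha_ci: tuple
    beta_ci: tuple
    pattern: str
    n: int
    log_likelihood: float

    @property
    def median(self) -> float:
        return self.alpha * math.log(2.0) ** (1.0 / self.beta)


@dataclass(frozen=True)
class TtoSummary:
    median: float
    q25: float
    q75: float
    n: int
    mann_whitney_p: float | None = None


# ---------------------------------------------------------------------------
# Latency extraction
# ---------------------------------------------------------------------------


def extract_latencies(
    reports: Sequence[Report],
    exposure: ExposureSpec,
    event: EventLabel,
    anchor: str = "target",
    label: str | None = None,
    where=None,
) -> LatencySample:
    """Collect latencies for the exposed cases of one exposure definition.

    ``anchor`` selects the therapy-start date defining t0: ``"target"``
    uses the earliest start among target-drug entries; ``"earliest"``
    the earliest among target-drug and required co-drug entries.  Cases
    with a missing start, a missing onset date, or a non-positive
    interval are excluded and tallied.  ``where`` optionally restricts
    the sample to exposed cases satisfying a report predicate (used to
    build complement subgroups for Mann-Whitney comparisons).
    """
    if anchor not in ("target", "earliest"):
        raise ValueError("anchor must be 'target' or 'earliest'")
    target = normalize_name(exposure.target_drug)
    anchored = {target}
    if anchor == "earliest":
        anchored |= {normalize_name(cd) for cd in exposure.co_drugs}
    tally = {"not_case": 0, "missing_start": 0, "missing_event": 0,
             "non_positive": 0}
    values = []
    for r in reports:
        if classify_report(r, exposure, event) != CLASS_EXPOSED_CASE:
            tally["not_case"] += 1
            continue
        if where is not None and not where(r):
            tally["not_case"] += 1
            continue
        starts = [
            d.therapy_start
            for d in r.drugs
            if normalize_name(d.name_std) in anchored and d.therapy_start
        ]
        if not starts:
            tally["missing_start"] += 1
            continue
        if r.event_date is None:
            tally["missing_event"] += 1
            continue
        days = (r.event_date - min(starts)).days
        if days <= 0:
            tally["non_positive"] += 1
            continue
        values.append(float(days))
    return LatencySample(
        label=label or exposure.describe(),
        values=np.array(values),
        n_excluded=tally,
    )


# ---------------------------------------------------------------------------
# Weibull maximum likelihood
# ---------------------------------------------------------------------------


def _weibull_nll(theta: np.ndarray, t: np.ndarray) -> float:
    log_a, log_b = theta
    a, b = math.exp(log_a), math.exp(log_b)
    z = t / a
    return -(
        len(t) * (math.log(b) - b * math.log(a))
        + (b - 1.0) * np.sum(np.log(t))
        - np.sum(z**b)
    )


def _mle(t: np.ndarray) -> tuple[float, float]:
    """Profile-likelihood MLE: solve the shape score equation, then the
    scale follows in closed form (alpha^beta = mean(t^beta)).

    The weighted-mean term is computed with shifted exponentials so large
    shapes cannot overflow; the root bracket expands until it straddles.
    """
    logs = np.log(t)
    mean_log = logs.mean()

    def score(beta: float) -> float:
        w = np.exp(beta * (logs - logs.max()))
        return 1.0 / beta + mean_log - float(np.sum(w * logs) / np.sum(w))

    lo, hi = 1e-3, 4.0
    while score(hi) > 0 and hi < 1e6:
        hi *= 2.0
    beta = optimize.brentq(score, lo, hi, xtol=1e-12)
    # alpha^beta = mean(t^beta), evaluated on the same shifted scale
    w = np.exp(beta * (logs - logs.max()))
    alpha = float(math.exp(logs.max() + math.log(np.mean(w)) / beta))
    return alpha, beta


def _observed_information(t: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Numerical Hessian of the negative log-likelihood in (log a, log b)."""
    theta = np.array([math.log(alpha), math.log(beta)])
    h = 1e-5
    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.eye(2)[i] * h
            ej = np.eye(2)[j] * h
            hess[i, j] = (
                _weibull_nll(theta + ei + ej, t)
                - _weibull_nll(theta + ei - ej, t)
                - _weibull_nll(theta - ei + ej, t)
                + _weibull_nll(theta - ei - ej, t)
            ) / (4.0 * h * h)
    return hess


def weibull_fit(sample: LatencySample | Sequence[float], z: float = Z_95) -> WeibullFit:
    """Two-parameter Weibull MLE with Wald CIs on the log scale.

    CIs come from the observed Fisher information at the MLE in
    (log alpha, log beta), back-transformed; the hazard-trend pattern is
    determined solely by the beta CI's position relative to 1.
    """
    if isinstance(sample, LatencySample):
        t = sample.values
    else:
        t = np.asarray(sample, dtype=float)
    if len(t) < MIN_SAMPLE:
        raise SmallSampleError(
            f"need at least {MIN_SAMPLE} latencies, got {len(t)}"
        )
    if np.min(t) <= 0:
        raise ValueError("latencies must be strictly positive")
    if np.ptp(t) == 0:
        raise ValueError("degenerate sample: all latencies identical")
    alpha, beta = _mle(t)
    info = _observed_information(t, alpha, beta)
    cov = np.linalg.inv(info)
    se_log_a, se_log_b = np.sqrt(np.diag(cov))
    alpha_ci = (alpha * math.exp(-z * se_log_a), alpha * math.exp(z * se_log_a))
    beta_ci = (beta * math.exp(-z * se_log_b), beta * math.exp(z * se_log_b))
    if beta_ci[1] < 1.0:
        pattern = PATTERN_EARLY
    elif beta_ci[0] > 1.0:
        pattern = PATTERN_WEAR_OUT
    else:
        pattern = PATTERN_RANDOM
    return WeibullFit(
        alpha=alpha,
        beta=beta,
        alpha_ci=alpha_ci,
        beta_ci=beta_ci,
        pattern=pattern,
        n=len(t),
        log_likelihood=-_weibull_nll(
            np.array([math.log(alpha), math.log(beta)]), t
        ),
    )


# ---------------------------------------------------------------------------
# Descriptive summary and subgroup comparison
# ---------------------------------------------------------------------------


def summarize_latency(
    sample: LatencySample, complement: LatencySample | None = None
) -> TtoSummary:
    """Median and IQR (linear-interpolation quartiles); optionally a
    Mann-Whitney comparison against the complement sample."""
    if sample.n == 0:
        raise ValueError("cannot summarize an empty latency sample")
    q25, med, q75 = np.percentile(sample.values, [25, 50, 75], method="linear")
    p = None
    if complement is not None and complement.n > 0:
        p = mann_whitney(sample.values, complement.values)
    return TtoSummary(median=float(med), q25=float(q25), q75=float(q75),
                      n=sample.n, mann_whitney_p=p)


def mann_whitney(sample_a, sample_b) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact null distribution when both samples have at most 8 values and
    no ties occur; otherwise the normal approximation with tie
    correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))
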
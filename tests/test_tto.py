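"""Latency extraction, Weibull shape-parameter test, Mann-Whitney U."""

import datetime as dt
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import faerspv as f
from faerspv import tto

from conftest import desk_config, make_report


def drug(name, role="PS", **kw):
    return f.DrugEntry(name_raw=name, name_std=name, role=role, **kw)


def _case(pid, start, onset, extra_drugs=()):
    return make_report(
        pid, pid, (2023, 1, 1),
        drugs=[drug("denosumab", therapy_start=start), *extra_drugs],
        events=["Osteonecrosis of jaw"],
        event_date=onset,
    )


class TestExtraction:
    def test_date_arithmetic(self, event, base_exposure):
        r = _case(1, dt.date(2020, 1, 1), dt.date(2020, 12, 31))
        sample = f.extract_latencies([r], base_exposure, event)
        assert sample.values.tolist() == [365.0]

    def test_event_before_start_excluded_as_non_positive(
        self, event, base_exposure
    ):
        r = _case(1, dt.date(2020, 6, 1), dt.date(2020, 1, 1))
        sample = f.extract_latencies([r], base_exposure, event)
        assert sample.n == 0
        assert sample.n_excluded["non_positive"] == 1

    def test_missing_dates_tallied(self, event, base_exposure):
        rs = [
            _case(1, None, dt.date(2020, 6, 1)),
            _case(2, dt.date(2020, 1, 1), None),
        ]
        sample = f.extract_latencies(rs, base_exposure, event)
        assert sample.n == 0
        assert sample.n_excluded["missing_start"] == 1
        assert sample.n_excluded["missing_event"] == 1

    def test_earliest_target_start_is_anchor(self, event, base_exposure):
        r = make_report(
            1, 1, (2023, 1, 1),
            drugs=[drug("denosumab", therapy_start=dt.date(2020, 3, 1)),
                   drug("denosumab", role="SS",
                        therapy_start=dt.date(2020, 1, 1))],
            events=["Osteonecrosis of jaw"],
            event_date=dt.date(2020, 1, 31),
        )
        # anchored on the earliest target-drug start (Jan 1), latency is 30 d
        sample = f.extract_latencies([r], base_exposure, event)
        assert sample.values.tolist() == [30.0]

    def test_anchor_switch_uses_co_drug_start(self, event):
        spec = f.ExposureSpec("denosumab",
                              co_drugs=frozenset({"zoledronic acid"}))
        r = make_report(
            1, 1, (2023, 1, 1),
            drugs=[drug("denosumab", therapy_start=dt.date(2020, 6, 1)),
                   drug("zoledronic acid", role="C",
                        therapy_start=dt.date(2020, 1, 1))],
            events=["Osteonecrosis of jaw"],
            event_date=dt.date(2020, 12, 1),
        )
        on_target = f.extract_latencies([r], spec, event, anchor="target")
        on_earliest = f.extract_latencies([r], spec, event, anchor="earliest")
        assert on_target.values.tolist() == [183.0]
        assert on_earliest.values.tolist() == [335.0]

    def test_extracted_values_equal_generator_truth(self, event,
                                                    base_exposure):
        cfg = desk_config(n_reports=5_000, seed=29, duplicate_rate=0.0)
        reports, gt = f.generate(cfg)
        sample = f.extract_latencies(reports, base_exposure, event)
        truth = gt.report_truth
        expected = truth.loc[
            truth.exposed & truth.is_case & ~truth.tto_masked, "latency_days"
        ]
        assert sorted(sample.values) == sorted(expected.tolist())


class TestWeibullFit:
    def test_parameter_recovery_at_reference_scale(self):
        rng = np.random.default_rng(7)
        t = 625.0 * rng.weibull(1.21, 1652)
        fit = f.weibull_fit(t)
        assert fit.beta_ci[0] <= 1.21 <= fit.beta_ci[1]
        assert fit.alpha == pytest.approx(625.0, rel=0.05)
        assert fit.pattern == "wear_out_failure"

    def test_matches_independent_mle(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(3)
        t = 500.0 * rng.weibull(0.9, 400)
        fit = f.weibull_fit(t)
        wf = lifelines.WeibullFitter().fit(t)
        assert fit.alpha == pytest.approx(wf.lambda_, rel=1e-5)
        assert fit.beta == pytest.approx(wf.rho_, rel=1e-5)

    @given(st.floats(0.01, 100.0))
    @settings(deadline=None, max_examples=25)
    def test_scale_equivariance(self, k):
        rng = np.random.default_rng(11)
        t = 300.0 * rng.weibull(1.4, 200)
        a = f.weibull_fit(t)
        b = f.weibull_fit(t * k)
        assert b.alpha == pytest.approx(a.alpha * k, rel=1e-7)
        assert b.beta == pytest.approx(a.beta, rel=1e-7)

    def test_median_identity_on_large_sample(self):
        rng = np.random.default_rng(13)
        t = 600.0 * rng.weibull(1.2, 20_000)
        fit = f.weibull_fit(t)
        assert fit.median == pytest.approx(float(np.median(t)), rel=0.03)

    def test_small_sample_refused(self):
        with pytest.raises(tto.SmallSampleError):
            f.weibull_fit(np.arange(1.0, 9.0))

    def test_degenerate_sample_refused(self):
        with pytest.raises(ValueError, match="degenerate"):
            f.weibull_fit(np.full(50, 100.0))

    def test_classification_is_a_partition(self):
        rng = np.random.default_rng(17)
        patterns = set()
        for beta in (0.5, 1.0, 2.0):
            t = 100.0 * rng.weibull(beta, 800)
            patterns.add(f.weibull_fit(t).pattern)
        assert patterns == {"early_failure", "random_failure",
                            "wear_out_failure"}

    def test_shape_recovery_median_error(self):
        errors = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            beta = 0.8 + 0.8 * (seed % 5) / 4  # sweep 0.8..1.6
            t = 500.0 * rng.weibull(beta, 500)
            errors.append(abs(f.weibull_fit(t).beta - beta))
        assert float(np.median(errors)) <= 0.1


class TestSummary:
    def test_median_of_three(self):
        s = tto.LatencySample("x", [100.0, 200.0, 300.0])
        assert f.summarize_latency(s).median == 200.0

    def test_linear_interpolation_quartiles(self):
        # type-7 convention on {1,2,3,4}: q25 = 1.75, median 2.5, q75 = 3.25
        s = tto.LatencySample("x", [1.0, 2.0, 3.0, 4.0])
        summary = f.summarize_latency(s)
        assert (summary.q25, summary.median, summary.q75) == (1.75, 2.5, 3.25)

    def test_quartile_ordering_invariant(self):
        rng = np.random.default_rng(19)
        s = tto.LatencySample("x", rng.uniform(1, 1000, 101))
        summary = f.summarize_latency(s)
        assert summary.q25 <= summary.median <= summary.q75

    def test_generator_sample_median_near_closed_form(self):
        cfg = desk_config(
            n_reports=30_000, seed=37, target_exposure_prob=0.5,
            true_log_or={"intercept": 0.0}, co_drug_probs={},
            latency_params={"all": (625.0, 1.21)},
            missing_rates={"age": 0, "sex": 0, "dose": 0, "reporter": 0,
                           "tto": 0},
            duplicate_rate=0.0,
        )
        _, gt = f.generate(cfg)
        lat = gt.report_truth.query("is_case")["latency_days"].dropna()
        expected = 625.0 * math.log(2) ** (1 / 1.21)
        assert np.median(lat) == pytest.approx(expected, rel=0.05)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            f.summarize_latency(tto.LatencySample("x", []))


class TestMannWhitney:
    def test_exact_p_matches_enumeration_oracle(self):
        a, b = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        p = f.mann_whitney(a, b)
        # oracle: enumerate all C(6,3) = 20 group assignments of the pooled
        # sample and count |U - n1*n2/2| at least as extreme
        pooled = sorted(a + b)
        n1 = len(a)
        u_obs = sum(1 for x in a for y in b if x > y) + \
            0.5 * sum(1 for x in a for y in b if x == y)
        center = len(a) * len(b) / 2
        stats = []
        for combo in itertools.combinations(range(len(pooled)), n1):
            ga = [pooled[i] for i in combo]
            gb = [pooled[i] for i in range(len(pooled)) if i not in combo]
            stats.append(sum(1 for x in ga for y in gb if x > y))
        p_exact = sum(1 for u in stats
                      if abs(u - center) >= abs(u_obs - center) - 1e-12) \
            / len(stats)
        assert p == pytest.approx(p_exact, abs=1e-12)
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_not_significant(self):
        assert f.mann_whitney([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(23)
        a = rng.uniform(1, 500, 40)
        b = rng.uniform(1, 800, 55)
        p1 = f.mann_whitney(a, b)
        p2 = f.mann_whitney(np.log(a), np.log(b))
        p3 = f.mann_whitney(a**3, b**3)
        assert p1 == pytest.approx(p2, rel=1e-12)
        assert p1 == pytest.approx(p3, rel=1e-12)

    def test_type_one_error_near_nominal(self):
        rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            a = 400.0 * rng.weibull(1.2, 60)
            b = 400.0 * rng.weibull(1.2, 80)
            rejections += f.mann_whitney(a, b) < 0.05
        # binomial 3-sigma band around 5% at 200 replicates
        assert rejections <= n_rep * 0.05 + 3 * math.sqrt(n_rep * 0.05 * 0.95)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            f.mann_whitney([], [1.0])
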
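"""Metrics: recall curves, RRF/WSS, Time to Discovery, aggregation.

Brute-force oracles recompute every metric straight from the raw event lists
(naive counting, no shared code with the implementation) and must agree
exactly.
"""

import math

import numpy as np
import pytest

from screensim import (
    MetricError,
    aggregate_models,
    aggregate_trials,
    mean_recall_curve,
    recall_curve,
    record_atd,
    rrf_at,
    simulation_atd,
    time_to_discovery,
    wss_at,
)

from conftest import make_result, random_order_result


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def brute_rrf(result, r, x_percent):
    cut = max(int(math.floor(x_percent / 100 * result.n_records)), 1)
    found = sum(lab for step, _, lab in result.events if step <= cut)
    return 100.0 * found / r


def brute_wss(result, r, level):
    found = 0
    for step, _, lab in result.events:
        found += lab
        if found / r >= level:
            return 100.0 * ((result.n_records - step) / result.n_records - (1 - level))
    raise AssertionError("level never reached")


def brute_record_atd(results, n):
    rel_ids = [rid for _, rid, lab in results[0].events if lab == 1]
    per_record = []
    for rid in rel_ids:
        tds = []
        for res in results:
            if rid in res.prior_ids:
                continue
            tds.append(next(s for s, i, _ in res.events if i == rid))
        if tds:
            per_record.append(sum(tds) / len(tds))
    return 100.0 * (sum(per_record) / len(per_record)) / n


def brute_simulation_atd(results, n):
    per_run = []
    for res in results:
        tds = [s for s, rid, lab in res.events if lab == 1 and rid not in res.prior_ids]
        if tds:
            per_run.append(sum(tds) / len(tds))
    return 100.0 * (sum(per_run) / len(per_run)) / n


# ---------------------------------------------------------------------------


class TestRecallCurve:
    def test_counting(self):
        result = make_result([1, 0, 1, 0])
        curve = recall_curve(result, 2)
        assert curve.recall == pytest.approx([0.5, 0.5, 1.0, 1.0])

    def test_all_relevant_first(self):
        result = make_result([1, 1, 1, 0, 0, 0])
        curve = recall_curve(result, 3)
        assert curve.recall[2] == 1.0 and (curve.recall[2:] == 1.0).all()

    def test_worst_case_order(self):
        result = make_result([0, 0, 0, 1, 1])
        curve = recall_curve(result, 2)
        assert (curve.recall[:3] == 0).all() and curve.recall[-1] == 1.0

    def test_relevant_count_mismatch_is_error(self):
        with pytest.raises(MetricError):
            recall_curve(make_result([1, 0, 1, 0]), 3)


class TestRRF:
    def test_hand_counted_window(self):
        # N=200, R=40, 12 relevant inside the first 20 steps -> RRF@10 = 30
        labels = [0] * 200
        for i in range(12):
            labels[i] = 1
        for i in range(20, 48):
            labels[i] = 1
        result = make_result(labels)
        assert rrf_at(result, 40, 10) == 30.0

    def test_perfect_ranking_inside_window(self):
        labels = [1] * 10 + [0] * 190
        assert rrf_at(make_result(labels), 10, 10) == 100.0

    def test_floor_of_window_at_least_one(self):
        labels = [1, 0, 0, 0, 0]
        assert rrf_at(make_result(labels), 1, 10) == 100.0  # floor(0.5) -> 1


class TestWSS:
    def test_hand_computed(self):
        # N=100, R=20, 19th relevant at step 30 -> WSS@95 = 65
        labels = [0] * 100
        for i in range(18):
            labels[i] = 1
        labels[29] = 1
        labels[99] = 1
        result = make_result(labels)
        assert wss_at(result, 20, 0.95) == pytest.approx(65.0)

    def test_evenly_spread_is_slightly_negative(self):
        # relevant at steps 10,20,...,100: full recall only at the last step
        labels = [1 if (i + 1) % 10 == 0 else 0 for i in range(100)]
        assert wss_at(make_result(labels), 10, 1.0) == pytest.approx(0.0)
        assert wss_at(make_result(labels), 10, 0.95) == pytest.approx(-5.0)

    def test_all_relevant_last_is_negative(self):
        labels = [0] * 95 + [1] * 5
        assert wss_at(make_result(labels), 5, 0.95) < 0


class TestTimeToDiscovery:
    def test_single_run_direct_read(self):
        result = make_result([1, 0, 1, 0])
        td = time_to_discovery([result], "r2")
        assert td.per_trial == {1: 3} and td.average_record_td == 3

    def test_average_over_runs(self):
        # record r2 labeled at step 3 in run 1 and step 5 in run 2 -> mean 4
        from screensim import ScreeningResult

        a = make_result([1, 0, 1, 0, 0], trial=1)
        events_b = ((1, "r0", 1), (2, "r1", 0), (3, "r3", 0), (4, "r4", 0), (5, "r2", 1))
        b = ScreeningResult(trial=2, seed=0, prior_ids=("r0", "r1"), events=events_b, n_records=5)
        td = time_to_discovery([a, b], "r2")
        assert td.average_record_td == 4.0

    def test_prior_trials_excluded(self):
        from screensim import ScreeningResult

        run1 = ScreeningResult(
            trial=1,
            seed=0,
            prior_ids=("r2", "r1"),
            events=((1, "r2", 1), (2, "r1", 0), (3, "r0", 1), (4, "r3", 0)),
            n_records=4,
        )
        events2 = ((1, "r0", 1), (2, "r1", 0), (3, "r3", 0), (4, "r2", 1))
        run2 = ScreeningResult(trial=2, seed=0, prior_ids=("r0", "r1"), events=events2, n_records=4)
        td = time_to_discovery([run1, run2], "r2")
        assert td.per_trial == {1: None, 2: 4}
        assert td.average_record_td == 4.0

    def test_irrelevant_record_is_metric_error(self):
        with pytest.raises(MetricError):
            time_to_discovery([make_result([1, 0, 1, 0])], "r1")


class TestATD:
    def test_single_record_single_run(self):
        labels = [1, 0, 1] + [0] * 7
        result = make_result(labels, with_priors=True)
        with pytest.warns(UserWarning, match="prior in every trial"):  # r0 excluded
            assert record_atd([result]) == pytest.approx(30.0)

    def test_two_records_arithmetic(self):
        labels = [0] * 10
        labels[0] = 1  # prior (excluded via with_priors)
        labels[2] = 1
        labels[6] = 1
        result = make_result(labels, with_priors=True)
        with pytest.warns(UserWarning, match="prior in every trial"):
            assert record_atd([result]) == pytest.approx(50.0)

    def test_single_run_orders_coincide(self):
        rng = np.random.default_rng(5)
        result = random_order_result(30, 6, rng)
        assert record_atd([result]) == pytest.approx(simulation_atd([result]))

    def test_complete_design_orders_coincide(self):
        # same labeled pool screened in five different orders, no priors
        # marked: every record defined in every run (Fubini)
        from screensim import ScreeningResult

        rng = np.random.default_rng(6)
        labels = {f"r{i}": (1 if i < 8 else 0) for i in range(40)}
        results = []
        for t in range(1, 6):
            order = rng.permutation(40)
            events = tuple((s + 1, f"r{i}", labels[f"r{i}"]) for s, i in enumerate(order))
            results.append(
                ScreeningResult(trial=t, seed=0, prior_ids=(), events=events, n_records=40)
            )
        assert record_atd(results) == pytest.approx(simulation_atd(results))

    def test_unbalanced_design_orders_differ(self):
        # N=5, relevant {r0, r2, r4}; different priors per run make the TD
        # design incomplete, so the two averaging orders disagree:
        # record-ATD: r0 -> {3}, r2 -> {3}, r4 -> {4,5} -> mean 3.5 -> 70%
        # simulation-ATD: run1 mean 3.5, run2 mean 4 -> 3.75 -> 75%
        from screensim import ScreeningResult

        run1 = ScreeningResult(
            trial=1,
            seed=0,
            prior_ids=("r0", "r1"),
            events=((1, "r0", 1), (2, "r1", 0), (3, "r2", 1), (4, "r4", 1), (5, "r3", 0)),
            n_records=5,
        )
        run2 = ScreeningResult(
            trial=2,
            seed=0,
            prior_ids=("r2", "r1"),
            events=((1, "r2", 1), (2, "r1", 0), (3, "r0", 1), (4, "r3", 0), (5, "r4", 1)),
            n_records=5,
        )
        rec = record_atd([run1, run2])
        sim = simulation_atd([run1, run2])
        assert rec == pytest.approx(70.0)
        assert sim == pytest.approx(75.0)
        assert rec == pytest.approx(brute_record_atd([run1, run2], 5))
        assert sim == pytest.approx(brute_simulation_atd([run1, run2], 5))

    def test_random_order_calibration_large_r(self):
        # asymptotically: mean ATD -> ~50, mean WSS@95 -> ~0 for large R
        rng = np.random.default_rng(123)
        n, r, trials = 400, 80, 200
        atds, wsss = [], []
        for _ in range(trials):
            res = random_order_result(n, r, rng)
            atds.append(simulation_atd([res]))
            wsss.append(wss_at(res, r, 0.95))
        assert np.mean(atds) == pytest.approx(50.0, abs=2.0)
        assert abs(np.mean(wsss)) < 3.0

    def test_better_ranking_never_hurts(self):
        # moving a relevant record strictly earlier improves every metric
        base = make_result([0, 0, 0, 1, 0, 1, 0, 0, 1, 0])
        better = make_result([0, 0, 1, 1, 0, 1, 0, 0, 0, 0])  # step-9 relevant moved to 3
        r = 3
        assert rrf_at(better, r, 30) >= rrf_at(base, r, 30)
        assert wss_at(better, r, 0.95) >= wss_at(base, r, 0.95)
        assert simulation_atd([better]) <= simulation_atd([base])


class TestOracleEquivalence:
    def test_metrics_match_brute_force_on_random_logs(self):
        rng = np.random.default_rng(777)
        for _ in range(60):
            n = int(rng.integers(5, 51))
            r = int(rng.integers(1, min(n - 1, 10) + 1))
            res = random_order_result(n, r, rng)
            assert rrf_at(res, r, 10) == brute_rrf(res, r, 10)
            assert wss_at(res, r, 0.95) == brute_wss(res, r, 0.95)
            assert record_atd([res]) == brute_record_atd([res], n)
            assert simulation_atd([res]) == brute_simulation_atd([res], n)


class TestAggregation:
    def test_trials_textbook(self):
        mean, sd, sem = aggregate_trials([1, 2, 3])
        assert (mean, sd) == (2.0, 1.0)
        assert sem == pytest.approx(1 / math.sqrt(3))

    def test_constant_values(self):
        assert aggregate_trials([4, 4, 4]) == (4.0, 0.0, 0.0)

    def test_single_value_dispersion_undefined(self):
        assert aggregate_trials([7.0]) == (7.0, None, None)

    def test_empty_is_error(self):
        with pytest.raises(MetricError):
            aggregate_trials([])

    def test_models_median_mad(self):
        assert aggregate_models([1, 2, 9]) == (2.0, 1.0)
        assert aggregate_models([5, 5, 5]) == (5.0, 0.0)

    def test_models_mad_brute_force_seven_values(self):
        vals = [66.2, 71.7, 64.9, 66.9, 70.9, 66.3, 71.6]
        med, mad = aggregate_models(vals)
        med_brute = sorted(vals)[3]
        mad_brute = sorted(abs(v - med_brute) for v in vals)[3]
        assert (med, mad) == (med_brute, mad_brute)


class TestMeanRecallCurve:
    def test_identical_trials_zero_band(self):
        res = make_result([1, 0, 1, 0])
        frame = mean_recall_curve([res, make_result([1, 0, 1, 0], trial=2)], 2)
        assert (frame["sem"] == 0).all()

    def test_pointwise_mean_and_sem_match_scalar_aggregator(self):
        rng = np.random.default_rng(2)
        results = [random_order_result(20, 4, rng, trial=t) for t in (1, 2, 3)]
        frame = mean_recall_curve(results, 4)
        from screensim import recall_curve as rc

        step = 9
        vals = [rc(r, 4).recall[step] for r in results]
        mean, _, sem = aggregate_trials(vals)
        assert frame["mean_recall"][step] == pytest.approx(mean)
        assert frame["sem"][step] == pytest.approx(sem)

    def test_mixed_n_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(MetricError):
            mean_recall_curve(
                [random_order_result(10, 2, rng), random_order_result(12, 2, rng, trial=2)], 2
            )
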
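"""Novelty statistic, selection rule, schedule control flow, and trainers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cbsnn import (NetworkConfig, ScheduleConfig, synth_clusters,
                   train_baseline, train_cbsnn, train_random_subset)
from cbsnn.curiosity import (NoveltyTable, TrainingLog, computation_ratio,
                             epoch_kind, novelty_estimate, select_samples)


class TestNoveltyEstimate:
    def test_parallel_orthogonal_antiparallel(self):
        v = np.array([0.3, 0.7])
        assert novelty_estimate(2.5 * v, v) == 0.0
        assert novelty_estimate(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 1.0
        assert novelty_estimate(-v, v) == 2.0

    def test_worked_example(self):
        ne = novelty_estimate(np.array([1.0, 0.0]), np.array([1.0, 1.0]))
        assert ne == pytest.approx(1 - 1 / math.sqrt(2), abs=1e-12)

    def test_silent_output_is_maximally_novel(self):
        assert novelty_estimate(np.zeros(3), np.array([1.0, 0, 0])) == 2.0

    def test_zero_teacher_rejected(self):
        with pytest.raises(ValueError):
            novelty_estimate(np.ones(2), np.zeros(2))

    @settings(max_examples=300, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=6),
           st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=6))
    def test_range_property(self, a, b):
        a, b = np.array(a), np.array(b)
        if a.size != b.size or np.linalg.norm(b) == 0:
            return
        assert 0.0 <= novelty_estimate(a, b) <= 2.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        v, t = rng.normal(size=4), rng.normal(size=4)
        assert novelty_estimate(v, t) == pytest.approx(
            novelty_estimate(10.0 * v, t), abs=1e-12)


class TestSelection:
    def test_boundary_is_selected(self):
        tab = NoveltyTable(NE=np.array([0.04, 0.05, 0.30]),
                           last_updated=np.zeros(3, int))
        assert list(select_samples(tab, 0.05)) == [1, 2]

    def test_zero_threshold_selects_all(self):
        tab = NoveltyTable(NE=np.random.default_rng(0).uniform(0, 2, 50),
                           last_updated=np.zeros(50, int))
        assert select_samples(tab, 0.0).size == 50

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(11)
        ne = rng.uniform(0, 2, 1000)
        tab = NoveltyTable(NE=ne, last_updated=np.zeros(1000, int))
        th = 0.7
        brute = [k for k in range(1000) if ne[k] >= th]
        assert list(select_samples(tab, th)) == brute


def simulate_schedule(T_start, I_re, n_epochs):
    """Independent trace of the four-phase control flow recursion."""
    kinds, e_0 = [], T_start
    for e in range(1, n_epochs + 1):
        if e <= T_start:
            kinds.append("full")
        elif e - e_0 == I_re:
            kinds.append("full")
            e_0 = e
        else:
            kinds.append("selective")
    return kinds


class TestEpochKind:
    def test_hand_trace_defaults(self):
        sched = ScheduleConfig(T_start=1, I_re=5, n_epochs=11)
        kinds, e_0 = [], sched.T_start
        for e in range(1, 12):
            kind, e_0 = epoch_kind(e, e_0, sched)
            kinds.append(kind)
        full_epochs = [i + 1 for i, k in enumerate(kinds) if k == "full"]
        assert full_epochs == [1, 6, 11]

    def test_unit_interval_every_epoch_full(self):
        sched = ScheduleConfig(T_start=1, I_re=1, n_epochs=8)
        e_0 = sched.T_start
        for e in range(1, 9):
            kind, e_0 = epoch_kind(e, e_0, sched)
            assert kind == "full"

    def test_seeding_epochs_full_regardless_of_interval(self):
        sched = ScheduleConfig(T_start=3, I_re=50, n_epochs=60)
        e_0 = sched.T_start
        for e in (1, 2, 3):
            kind, e_0 = epoch_kind(e, e_0, sched)
            assert kind == "full"

    def test_matches_independent_recursion(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            T_start = int(rng.integers(1, 6))
            I_re = int(rng.integers(1, 9))
            n_epochs = int(rng.integers(T_start, 40))
            sched = ScheduleConfig(T_start=T_start, I_re=I_re, n_epochs=n_epochs)
            e_0, kinds = T_start, []
            for e in range(1, n_epochs + 1):
                kind, e_0 = epoch_kind(e, e_0, sched)
                kinds.append(kind)
            assert kinds == simulate_schedule(T_start, I_re, n_epochs)
            # closed-form count of full epochs
            expected_full = T_start + (n_epochs - T_start) // I_re
            assert kinds.count("full") == expected_full

    def test_schedule_config_validation(self):
        with pytest.raises(ValueError):
            ScheduleConfig(T_start=0)
        with pytest.raises(ValueError):
            ScheduleConfig(NE_th=2.5)
        with pytest.raises(ValueError):
            ScheduleConfig(n_epochs=2, T_start=5)


def make_log(sizes, dataset_size):
    log = TrainingLog(dataset_size=dataset_size)
    for e, s in enumerate(sizes, start=1):
        log.append(e, "full" if s == dataset_size else "selective", s, 0.0, 0.0)
    return log


class TestComputationRatio:
    def test_hand_computed_example(self):
        # 10 epochs: 2 full of size N, 8 selective of N/2 -> 6N / 10N = 0.6
        N = 100
        cb = make_log([N] + [N // 2] * 4 + [N] + [N // 2] * 4, N)
        base = make_log([N] * 10, N)
        assert computation_ratio(cb, base) == pytest.approx(0.6)

    def test_identical_schedules_ratio_one(self):
        base = make_log([50] * 5, 50)
        assert computation_ratio(base, make_log([50] * 5, 50)) == 1.0

    def test_monotone_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(5)
        tab = NoveltyTable(NE=rng.uniform(0, 2, 300),
                           last_updated=np.zeros(300, int))
        counts = [select_samples(tab, th).size
                  for th in np.linspace(0, 2, 21)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_mismatched_logs_rejected(self):
        with pytest.raises(ValueError):
            computation_ratio(make_log([10] * 3, 10), make_log([10] * 4, 10))
        with pytest.raises(ValueError):
            computation_ratio(make_log([10] * 3, 10), make_log([20] * 3, 20))

    def test_cumulative_is_running_sum(self):
        log = make_log([5, 3, 7], 10)
        cums = [r["cumulative"] for r in log.records]
        assert cums == [5, 8, 15]
        assert log.cumulative_presentations == 15


class TestTrainers:
    def test_zero_threshold_reproduces_baseline_bitwise(self, small_task,
                                                        small_config):
        train, _ = small_task
        sched = ScheduleConfig(NE_th=0.0, n_epochs=5)
        net_c, log_c, _ = train_cbsnn(train, small_config, sched, seed=3)
        net_b, log_b, _ = train_baseline(train, small_config, 5, seed=3)
        assert np.array_equal(net_c.W1.W, net_b.W1.W)
        assert np.array_equal(net_c.W2.W, net_b.W2.W)
        cols = ["selected", "presentations", "cumulative", "loss", "accuracy"]
        assert log_c.to_dataframe()[cols].equals(log_b.to_dataframe()[cols])

    def test_schedule_ending_at_t_start_equals_baseline(self, small_task,
                                                        small_config):
        train, _ = small_task
        sched = ScheduleConfig(T_start=2, n_epochs=2)
        net_c, _, _ = train_cbsnn(train, small_config, sched, seed=1)
        net_b, _, _ = train_baseline(train, small_config, 2, seed=1)
        assert np.array_equal(net_c.W2.W, net_b.W2.W)

    def test_high_threshold_trains_nothing_selectively(self, small_task,
                                                       small_config):
        train, _ = small_task
        sched = ScheduleConfig(NE_th=1.99, n_epochs=4)
        _, log, _ = train_cbsnn(train, small_config, sched, seed=1)
        kinds = [r["kind"] for r in log.records]
        sel = [r["selected"] for r in log.records]
        assert kinds == ["full", "selective", "selective", "selective"]
        # near-max threshold: selective epochs may legitimately be empty,
        # and empty epochs are logged (selected 0), not an error
        assert all(s == train.n_samples for k, s in zip(kinds, sel) if k == "full")
        assert all(s <= train.n_samples // 4 for k, s in zip(kinds, sel)
                   if k == "selective")

    def test_presentations_below_baseline_when_samples_learned(
            self, small_task, small_config, short_schedule):
        train, _ = small_task
        _, log_c, tab = train_cbsnn(train, small_config, short_schedule, seed=3)
        _, log_b, _ = train_baseline(train, small_config,
                                     short_schedule.n_epochs, seed=3)
        if np.any(tab.NE < short_schedule.NE_th):
            assert (log_c.cumulative_presentations
                    < log_b.cumulative_presentations)

    def test_novelty_bounds_hold_after_training(self, small_task,
                                                small_config, short_schedule):
        train, _ = small_task
        _, _, tab = train_cbsnn(train, small_config, short_schedule, seed=2)
        assert np.all(tab.NE >= 0) and np.all(tab.NE <= 2)
        assert tab.NE.size == train.n_samples

    def test_log_invariants(self, small_task, small_config, short_schedule):
        train, _ = small_task
        _, log, _ = train_cbsnn(train, small_config, short_schedule, seed=2)
        for rec in log.records:
            if rec["kind"] == "full":
                assert rec["selected"] == train.n_samples
        cums = np.cumsum([r["presentations"] for r in log.records])
        assert list(cums) == [r["cumulative"] for r in log.records]

    def test_random_subset_presentation_count(self, small_task, small_config):
        train, _ = small_task
        _, log, _ = train_random_subset(train, small_config, n_epochs=4,
                                        subset_fraction=0.5, seed=1)
        expected = round(0.5 * train.n_samples)
        assert all(r["selected"] == expected for r in log.records)

    def test_fixed_subset_is_constant_across_epochs(self, small_task,
                                                    small_config):
        train, _ = small_task
        _, log, tab = train_random_subset(train, small_config, n_epochs=3,
                                          subset_fraction=0.3, seed=1,
                                          fixed_subset=True)
        # samples outside the fixed subset are never scored
        untouched = np.sum(tab.last_updated == 0)
        assert untouched == train.n_samples - round(0.3 * train.n_samples)

    def test_label_exceeding_output_width_rejected(self, small_task):
        train, _ = small_task
        cfg = NetworkConfig(layer_sizes=(4, 8, 2), T=10)
        with pytest.raises(ValueError):
            train_baseline(train, cfg, 1, seed=0)
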
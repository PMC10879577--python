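"""Travel schedules, batching, local updates and the two training loops."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from travelnet._seeds import derive_seed
from travelnet.cohort import Cohort, SplitCohort
from travelnet.engine import (
    EarlyStopping,
    SchedulePolicy,
    TrainConfig,
    local_update,
    make_batches,
    make_travel_schedule,
    run_centralized,
    run_traveling,
)
from travelnet.network import ModelConfig, build_model
from travelnet.nn import Adam

from conftest import TINY_MODEL


class TestSchedules:
    def test_fixed_mode_reuses_one_permutation(self):
        ids = [f"c{i}" for i in range(10)]
        policy = SchedulePolicy(mode="fixed", base_seed=42)
        first = make_travel_schedule(ids, policy, 1)
        assert make_travel_schedule(ids, policy, 7) == first

    def test_random_mode_redraws_reproducibly_per_cycle(self):
        ids = ["a", "b", "c"]
        policy = SchedulePolicy(mode="random", base_seed=42)
        s1 = make_travel_schedule(ids, policy, 1)
        s2 = make_travel_schedule(ids, policy, 2)
        # replaying the documented Fisher-Yates with the cycle seeds 42, 43
        for cycle, expected in ((1, s1), (2, s2)):
            out = sorted(ids)
            rng = np.random.Generator(np.random.PCG64(42 + cycle - 1))
            for i in range(len(out) - 1, 0, -1):
                j = int(rng.integers(0, i + 1))
                out[i], out[j] = out[j], out[i]
            assert out == expected

    def test_single_center(self):
        for mode in ("fixed", "random"):
            assert make_travel_schedule(["c"], SchedulePolicy(mode=mode), 5) == ["c"]

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            make_travel_schedule([], SchedulePolicy(), 1)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        n=st.integers(2, 40),
        cycle=st.integers(1, 60),
        base=st.integers(0, 10_000),
        mode=st.sampled_from(["fixed", "random"]),
    )
    def test_schedule_is_always_a_permutation(self, n, cycle, base, mode):
        ids = [f"center-{i}" for i in range(n)]
        out = make_travel_schedule(ids, SchedulePolicy(mode=mode, base_seed=base), cycle)
        assert sorted(out) == sorted(ids)


class TestBatches:
    def test_small_center_one_batch(self, small_cohort):
        recs = small_cohort.records[:3]
        batches = make_batches(recs, 5, np.random.default_rng(0))
        assert [len(b) for b in batches] == [3]

    def test_partial_final_batch(self, small_cohort):
        recs = small_cohort.records[:12]
        batches = make_batches(recs, 5, np.random.default_rng(0))
        assert [len(b) for b in batches] == [5, 5, 2]

    def test_batches_partition_center(self, small_cohort):
        rng = np.random.default_rng(1)
        for trial in range(50):
            n = int(rng.integers(1, 25))
            recs = (small_cohort.records * 2)[:n]
            recs = [replace(r, participant_id=f"{r.participant_id}-{i}") for i, r in enumerate(recs)]
            batches = make_batches(recs, 5, np.random.default_rng(trial))
            seen = [r.participant_id for b in batches for r in b]
            assert sorted(seen) == sorted(r.participant_id for r in recs)


class TestAdam:
    def test_single_step_matches_closed_form(self):
        # one step on a scalar: m=(1-b1)g, v=(1-b2)g^2, with bias correction
        # m_hat=g, v_hat=g^2 -> p' = p - lr*g/(|g|+eps)
        p = {"w": np.array([1.5], dtype=np.float32)}
        g = {"w": np.array([0.3], dtype=np.float32)}
        opt = Adam(["w"])
        opt.step(p, g, lr=0.01)
        expected = 1.5 - 0.01 * 0.3 / (np.sqrt(0.3**2) + 1e-8)
        assert p["w"][0] == pytest.approx(expected, rel=1e-6)

    def test_two_steps_match_manual_recursion(self):
        lr, b1, b2, eps = 0.05, 0.9, 0.999, 1e-8
        p = {"w": np.array([0.7], dtype=np.float32)}
        opt = Adam(["w"])
        grads = [0.2, -0.4]
        manual, m, v = 0.7, 0.0, 0.0
        for t, g in enumerate(grads, start=1):
            opt.step(p, {"w": np.array([g], dtype=np.float32)}, lr=lr)
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            manual -= lr * (m / (1 - b1**t)) / (np.sqrt(v / (1 - b2**t)) + eps)
        assert p["w"][0] == pytest.approx(manual, rel=1e-5)


class TestLocalUpdate:
    def test_lr_zero_leaves_model_unchanged(self, small_cohort, small_volumes, tiny_model):
        before = {k: v.copy() for k, v in tiny_model.named_params().items()}
        opt = tiny_model.make_optimizer()
        recs = small_cohort.records[:8]
        local_update(tiny_model, opt, recs, small_volumes, 1, 0.0, 5, [123])
        for k, v in tiny_model.named_params().items():
            assert np.array_equal(v, before[k])

    def test_two_epochs_equal_two_chained_single_epochs(self, small_cohort, small_volumes):
        recs = small_cohort.records[:8]
        seeds = [derive_seed(0, "e", 1), derive_seed(0, "e", 2)]

        m1 = build_model(TINY_MODEL)
        o1 = m1.make_optimizer()
        local_update(m1, o1, recs, small_volumes, 2, 1e-3, 5, seeds)

        m2 = build_model(TINY_MODEL)
        o2 = m2.make_optimizer()
        local_update(m2, o2, recs, small_volumes, 1, 1e-3, 5, seeds[:1])
        local_update(m2, o2, recs, small_volumes, 1, 1e-3, 5, seeds[1:])

        for k, v in m1.named_params().items():
            assert np.array_equal(v, m2.named_params()[k])

    def test_seed_count_must_match_epochs(self, small_cohort, small_volumes, tiny_model):
        with pytest.raises(ValueError):
            local_update(
                tiny_model, tiny_model.make_optimizer(),
                small_cohort.records[:4], small_volumes, 2, 1e-3, 5, [1],
            )


class TestEarlyStopping:
    def test_scripted_rise_stops_after_patience_epochs(self):
        # loss 0.5 at epoch 1, then strictly rising: stop after epoch 11
        stopper = EarlyStopping(patience=10)
        losses = [0.5] + [0.6 + 0.01 * i for i in range(15)]
        stopped_at = None
        for epoch, loss in enumerate(losses, start=1):
            if stopper.update(epoch, loss):
                stopped_at = epoch
                break
        assert stopped_at == 11
        assert stopper.best_epoch == 1

    def test_improvement_resets_counter(self):
        stopper = EarlyStopping(patience=2)
        assert not stopper.update(1, 1.0)
        assert not stopper.update(2, 1.1)
        assert not stopper.update(3, 0.9)  # improvement
        assert not stopper.update(4, 1.2)
        assert stopper.update(5, 1.3)
        assert stopper.best_epoch == 3


class TestTrainingLoops:
    def test_zero_cycles_leaves_model_unchanged(self, small_split, small_volumes):
        model = build_model(TINY_MODEL)
        before = {k: v.copy() for k, v in model.named_params().items()}
        cfg = TrainConfig.traveling_default(max_cycles=0, data_seed=1)
        history = run_traveling(model, small_split, small_volumes, cfg)
        assert len(history) == 0
        for k, v in model.named_params().items():
            assert np.array_equal(v, before[k])

    def test_lr_decays_exponentially_per_cycle(self, small_split, small_volumes):
        model = build_model(TINY_MODEL)
        cfg = TrainConfig.traveling_default(
            max_cycles=3, data_seed=1, initial_lr=1e-3, lr_decay_factor=0.9
        )
        history = run_traveling(model, small_split, small_volumes, cfg)
        lrs = [e.lr for e in history.entries]
        assert lrs == pytest.approx([1e-3, 9e-4, 8.1e-4])

    def test_every_cycle_schedule_is_permutation_of_training_centers(
        self, small_split, small_volumes
    ):
        model = build_model(TINY_MODEL)
        cfg = TrainConfig.traveling_default(max_cycles=3, data_seed=1)
        history = run_traveling(model, small_split, small_volumes, cfg)
        centers = sorted(small_split.train.centers.keys())
        for entry in history.entries:
            assert sorted(entry.schedule) == centers

    def test_exposure_conservation(self, small_split, small_volumes):
        cycles, epochs = 3, 2
        model = build_model(TINY_MODEL)
        cfg = TrainConfig.traveling_default(
            max_cycles=cycles, local_epochs=epochs, data_seed=1
        )
        history = run_traveling(model, small_split, small_volumes, cfg)
        assert set(history.exposure_counts) == set(small_split.train.participant_ids())
        assert all(c == cycles * epochs for c in history.exposure_counts.values())

    def test_centralized_is_deterministic(self, small_split, small_volumes):
        histories = []
        for _ in range(2):
            model = build_model(TINY_MODEL)
            cfg = TrainConfig.centralized_default(max_cycles=3, data_seed=9)
            histories.append(run_centralized(model, small_split, small_volumes, cfg))
        a, b = histories
        assert a.to_frame().equals(b.to_frame())

    def test_single_center_traveling_equals_centralized(self, small_cohort, small_volumes):
        """Oracle: with one center the two loops are the same update sequence."""
        merged = Cohort(tuple(replace(r, center_id="only") for r in small_cohort.records))
        train = Cohort(merged.records[:18])
        test = Cohort(tuple(replace(r, split="test") for r in merged.records[18:]))
        split = SplitCohort(train=train, test=test, split_report=None)

        mt = build_model(TINY_MODEL)
        ht = run_traveling(
            mt, split, small_volumes,
            TrainConfig.traveling_default(max_cycles=2, data_seed=4, initial_lr=1e-3),
        )
        mc = build_model(TINY_MODEL)
        hc = run_centralized(
            mc, split, small_volumes,
            TrainConfig.centralized_default(
                max_cycles=2, data_seed=4, initial_lr=1e-3,
                early_stopping_patience=None, pooled_center_key="only",
            ),
        )
        for k, v in mt.named_params().items():
            assert np.array_equal(v, mc.named_params()[k])
        assert ht.aurocs == hc.aurocs

    def test_history_csv_round_trip(self, tmp_path, small_split, small_volumes):
        model = build_model(TINY_MODEL)
        cfg = TrainConfig.traveling_default(max_cycles=2, data_seed=1)
        history = run_traveling(model, small_split, small_volumes, cfg)
        path = tmp_path / "history.csv"
        history.to_csv(path)
        from travelnet.engine import History

        back = History.from_csv(path)
        assert back.aurocs == pytest.approx(history.aurocs)
        assert [e.schedule for e in back.entries] == [e.schedule for e in history.entries]
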
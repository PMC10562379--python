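import numpy as np
import pytest

from membandit import (
    RewardWalkConfig,
    assign_lure_opposed_walks,
    build_schedule,
    generate_reward_walk,
)
from membandit.task import ConfigError


class TestWalkConfig:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"stickiness": 1.0}, "stickiness"),
            ({"lower_bound": 50.0, "upper_bound": 40.0}, "bound"),
            ({"initial_targets": (60.0, 60.0, 10.0)}, "initial_targets"),
            ({"rotation_period": 0}, "rotation_period"),
            ({"noise_sd": -1.0}, "noise_sd"),
        ],
    )
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            RewardWalkConfig(**kwargs).validate()


class TestRewardWalk:
    def test_zero_noise_fixed_point(self, schedule_v1):
        """With no diffusion noise and pi0 = theta, theta is a fixed point
        of the recursion: the walk sits exactly on its centers when they
        never rotate."""
        cfg = RewardWalkConfig(noise_sd=0.0, rotation_first_trial=10**9)
        series = generate_reward_walk(cfg, schedule_v1, seed=0)
        assert np.allclose(series.payout_prob, series.target_center)

    def test_one_step_hand_value(self):
        """pi1 = 0.6*90 + 0.4*60 = 78 for a zero-noise walk started at 90."""
        lam, pi0, theta = 0.6, 90.0, 60.0
        assert lam * pi0 + (1 - lam) * theta == pytest.approx(78.0)
        # and the generator implements exactly that recursion
        sched = build_schedule(1, seed=0)
        cfg = RewardWalkConfig(noise_sd=0.0)
        series = generate_reward_walk(cfg, sched, seed=0)
        t = 20  # interior trial away from rotation and room boundaries
        expected = (
            0.6 * series.payout_prob[:, t - 1] + 0.4 * series.target_center[:, t]
        )
        assert np.allclose(series.payout_prob[:, t], expected)

    def test_reflecting_bounds_long_run(self):
        """Payouts never leave [5, 95] over a 10,000-trial extension."""
        sched = build_schedule(1, seed=3, n_learning_trials=9000,
                               n_probe_phase_choice_trials=1000)
        series = generate_reward_walk(RewardWalkConfig(), sched, seed=4)
        assert series.payout_prob.min() >= 5.0
        assert series.payout_prob.max() <= 95.0

    def test_stationary_mean_tracks_center(self):
        """With lam=0.6 and no rotation the within-block mean approaches
        the target center within 3 percentage points."""
        sched = build_schedule(1, seed=5, n_learning_trials=5010,
                               n_probe_phase_choice_trials=0,
                               n_old_probes=0, n_novel_probes=0)
        cfg = RewardWalkConfig(rotation_first_trial=10**9)
        series = generate_reward_walk(cfg, sched, seed=6)
        # At default noise the reflecting bound at 5 inflates the mean of
        # the theta=10 deck; the unbounded-regime deck must be unbiased.
        mid = int(np.argmax(series.target_center[:, 0] == 60.0))
        assert abs(series.payout_prob[mid, 10:].mean() - 60.0) < 3.0
        # With noise small enough that the bounds never bind, every deck's
        # long-run mean reverts to its center.
        quiet = generate_reward_walk(
            RewardWalkConfig(noise_sd=2.0, rotation_first_trial=10**9), sched, seed=8
        )
        for deck in range(3):
            theta = quiet.target_center[deck, 0]
            assert abs(quiet.payout_prob[deck, 10:].mean() - theta) < 3.0

    def test_rotation_changes_top_deck_and_permutes_centers(self, schedule_v1):
        series = generate_reward_walk(RewardWalkConfig(), schedule_v1, seed=7)
        targets = sorted(RewardWalkConfig().initial_targets)
        rotations = range(10, series.n_trials, 30)
        for t in rotations:
            assert np.argmax(series.target_center[:, t]) != np.argmax(
                series.target_center[:, t - 1]
            )
        for t in range(series.n_trials):
            assert sorted(series.target_center[:, t]) == targets

    def test_seed_determinism(self, schedule_v1):
        cfg = RewardWalkConfig()
        a = generate_reward_walk(cfg, schedule_v1, seed=9)
        b = generate_reward_walk(cfg, schedule_v1, seed=9)
        assert np.array_equal(a.payout_prob, b.payout_prob)
        assert np.array_equal(a.target_center, b.target_center)

    def test_full_payout_room_start_variant(self, schedule_v1):
        cfg = RewardWalkConfig(room_start_full_payout=True)
        series = generate_reward_walk(cfg, schedule_v1, seed=10)
        for room in range(6):
            for t in range(room * 30, room * 30 + 3):
                top = np.argmax(series.target_center[:, t])
                assert series.payout_prob[top, t] == 100.0


class TestSchedule:
    def test_variant1_structure(self, schedule_v1):
        s = schedule_v1
        assert s.n_learning_trials == 180
        assert s.n_rooms == 6
        assert s.n_probe_phase_choice_trials == 120
        assert s.n_probes == 60
        assert (s.probe_items >= 0).sum() == 50
        assert (s.probe_items < 0).sum() == 10
        assert len(np.unique(s.context_ids)) == 6

    def test_old_probes_from_first_ten_room_trials(self):
        for seed in range(5):
            for variant in (1, 2):
                s = build_schedule(variant, seed=seed)
                old = s.probe_items[s.probe_items >= 0]
                assert np.all(old % s.room_length < 10)

    def test_probe_placement_constraints(self):
        for seed in range(5):
            s = build_schedule(1, seed=seed)
            pos = s.probe_positions
            assert np.all(np.diff(pos) >= 2)
            assert pos[-1] < s.n_phase2_events - 1

    def test_probes_spread_evenly_across_rooms(self, schedule_v1):
        old = schedule_v1.probe_items[schedule_v1.probe_items >= 0]
        counts = np.bincount(old // 30, minlength=6)
        assert set(counts) <= {8, 9}

    def test_variant2_category_layout(self):
        for seed in range(10):
            s = build_schedule(2, seed=seed)
            cats = s.context_category
            assert sorted(cats[:3]) == [0, 1, 2]
            assert sorted(cats[3:]) == [0, 1, 2]
            assert cats[2] != cats[3]

    def test_schedule_determinism(self):
        a = build_schedule(2, seed=42)
        b = build_schedule(2, seed=42)
        assert np.array_equal(a.probe_positions, b.probe_positions)
        assert np.array_equal(a.probe_items, b.probe_items)
        assert np.array_equal(a.context_ids, b.context_ids)

    def test_post_probe_map_points_at_preceding_probe(self, schedule_v1):
        m = schedule_v1.post_probe_map()
        assert (m >= 0).sum() == schedule_v1.n_probes
        kinds = schedule_v1.phase2_event_kind()
        choice_events = np.flatnonzero(~kinds)
        for j, k in enumerate(m):
            if k >= 0:
                assert schedule_v1.probe_positions[k] == choice_events[j] - 1


class TestLureOpposition:
    def test_opposition_holds_for_all_pairs(self, schedule_v2, walk_v2):
        series = assign_lure_opposed_walks(walk_v2, schedule_v2)
        for a, b in schedule_v2.category_pairs():
            top_a = series.modal_top_deck(slice(a * 30, (a + 1) * 30))
            top_b = series.modal_top_deck(slice(b * 30, (b + 1) * 30))
            assert top_a != top_b

    def test_variant1_schedule_rejected(self, schedule_v1, walk_v1):
        with pytest.raises(ValueError, match="variant-2"):
            assign_lure_opposed_walks(walk_v1, schedule_v1)

    def test_opposition_on_degenerate_zero_noise_walk(self, schedule_v2):
        cfg = RewardWalkConfig(noise_sd=0.0)
        series = generate_reward_walk(cfg, schedule_v2, seed=1)
        assign_lure_opposed_walks(series, schedule_v2)  # no error
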
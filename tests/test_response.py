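"""Vocal/non-vocal trajectory machinery: windows, matching, acceleration,
paired tests, subsampling, epochs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from squeaktrace import (
    ArenaConfig,
    BehaviorParams,
    Tracks,
    VocalEvent,
    build_control_pool,
    build_vocal_trajectories,
    compute_speeds,
    epoch_analysis,
    inject_response_kick,
    match_controls,
    post_acceleration,
    simulate_dyad,
    stratum_test,
    subsample_null,
)
from squeaktrace.response import (
    MatchedPair,
    VocalTrajectory,
    acceleration_window_ms,
    trajectory_span_ms,
)


def _event(t, vocalizer=1):
    return VocalEvent(t, vocalizer, np.array([5.0, 5.0]),
                      np.array([[0.0, 60e3], [0.03, 60e3]]))


def _speeds_dist(n, v1=6.0, v2=3.0, dist=5.0):
    speeds = np.column_stack([np.full(n, v1), np.full(n, v2)])
    speeds[0] = np.nan
    return speeds, np.full(n, dist)


class TestWindows:
    def test_window_arithmetic(self):
        assert trajectory_span_ms() == 367
        assert acceleration_window_ms() == 167

    def test_stationary_and_uniform_speeds(self):
        c = np.zeros((10, 2))
        assert np.nanmax(compute_speeds(c)) == 0.0
        c2 = np.column_stack([np.arange(10.0), np.zeros(10)])  # 1 cm/frame
        np.testing.assert_allclose(compute_speeds(c2)[1:], 30.0)

    def test_distance_rule_excludes_far_events(self):
        speeds, dist = _speeds_dist(300, dist=25.0)
        trajs, qc = build_vocal_trajectories([_event(3.0)], speeds, dist)
        assert trajs == [] and qc["proximity"] == 1

    def test_two_close_events_both_non_isolated(self):
        speeds, dist = _speeds_dist(300)
        trajs, _ = build_vocal_trajectories([_event(3.0), _event(3.2)], speeds, dist)
        assert len(trajs) == 2
        assert all(not t.isolated for t in trajs)
        solo, _ = build_vocal_trajectories([_event(3.0)], speeds, dist)
        assert solo[0].isolated

    def test_relative_speed_classification(self):
        speeds, dist = _speeds_dist(300, v1=10.0, v2=5.0)
        trajs, _ = build_vocal_trajectories([_event(3.0, vocalizer=1)], speeds, dist)
        assert trajs[0].relative_speed == "faster"
        trajs2, _ = build_vocal_trajectories([_event(3.0, vocalizer=2)], speeds, dist)
        assert trajs2[0].relative_speed == "slower"
        # exact tie -> slower by convention
        tie, _ = build_vocal_trajectories(
            [_event(3.0)], *_speeds_dist(300, v1=5.0, v2=5.0)
        )
        assert tie[0].relative_speed == "slower"

    def test_edge_events_dropped(self):
        speeds, dist = _speeds_dist(100)
        trajs, qc = build_vocal_trajectories(
            [_event(0.05), _event(99.8 / 30.0)], speeds, dist
        )
        assert trajs == [] and qc["edge"] == 2

    def test_undefined_speed_drops_trajectory(self):
        speeds, dist = _speeds_dist(300)
        speeds[92, 1] = np.nan  # inside the receiver window of an event at frame 90
        trajs, qc = build_vocal_trajectories([_event(90.5 / 30.0)], speeds, dist)
        assert trajs == [] and qc["undefined_speed"] == 1


class TestControlPool:
    def test_pool_size_without_events(self):
        s = np.full(100, 4.0)
        s[0] = np.nan
        starts, windows = build_control_pool(s, [])
        # windows start at 1..89: n - 10 candidates minus the one touching
        # the undefined frame-0 speed
        assert len(starts) == 89
        assert windows.shape == (89, 11)

    def test_event_removes_overlapping_windows(self):
        s = np.full(100, 4.0)
        s[0] = np.nan
        starts, _ = build_control_pool(s, [50])
        assert len(starts) == 89 - 11
        assert all(not (w <= 50 <= w + 10) for w in starts)

    def test_fully_masked_speeds_give_empty_pool(self):
        starts, _ = build_control_pool(np.full(50, np.nan), [])
        assert len(starts) == 0

    def test_optional_proximity_filter(self):
        s = np.full(100, 4.0)
        s[0] = np.nan
        dist = np.full(100, 30.0)
        dist[40:60] = 10.0  # close only there
        starts, _ = build_control_pool(s, [], dist=dist, proximity_cm=20.0)
        assert len(starts) > 0
        assert all(40 <= w + 5 < 60 for w in starts)


def _traj(samples, frame=100):
    return VocalTrajectory(
        samples=np.asarray(samples, float), emission_frame=frame, vocalizer=1,
        receiver=2, relative_speed="faster", epoch=1, isolated=True,
        event_time=frame / 30.0,
    )


class TestMatching:
    def test_exact_copy_is_chosen_with_zero_cost(self):
        rng = np.random.default_rng(0)
        pool = rng.uniform(0, 10, (30, 11))
        traj = _traj(np.concatenate([pool[17, :6], [9, 9, 9, 9, 9]]))
        pairs, _ = match_controls([traj], np.arange(30), pool)
        assert pairs[0].control_start == 17
        assert pairs[0].match_cost == 0.0

    def test_controls_used_at_most_once(self):
        rng = np.random.default_rng(1)
        pool = rng.uniform(0, 10, (40, 11))
        trajs = [_traj(rng.uniform(0, 10, 11), frame=100 + i) for i in range(25)]
        pairs, unmatched = match_controls(trajs, np.arange(40), pool)
        starts = [p.control_start for p in pairs]
        assert len(starts) == len(set(starts)) == 25
        assert unmatched == []

    def test_pool_exhaustion_reported(self):
        rng = np.random.default_rng(2)
        pool = rng.uniform(0, 10, (3, 11))
        trajs = [_traj(rng.uniform(0, 10, 11), frame=100 + i) for i in range(5)]
        pairs, unmatched = match_controls(trajs, np.arange(3), pool)
        assert len(pairs) == 3 and len(unmatched) == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_greedy_matches_sequential_brute_force(self, seed):
        """Oracle: per trajectory in chronological order, exhaustively scan
        every remaining window for the minimum cost (earliest on ties)."""
        rng = np.random.default_rng(seed)
        n_pool = rng.integers(5, 21)
        n_traj = rng.integers(2, n_pool + 1)
        pool = np.round(rng.uniform(0, 4, (n_pool, 11)), 1)  # coarse -> ties happen
        trajs = [_traj(np.round(rng.uniform(0, 4, 11), 1), frame=50 + i)
                 for i in range(n_traj)]

        remaining = list(range(n_pool))
        expected = []
        for traj in trajs:
            best, best_cost = None, np.inf
            for idx in remaining:
                cost = float(np.abs(pool[idx, :6] - traj.samples[:6]).sum())
                if cost < best_cost - 1e-9:
                    best, best_cost = idx, cost
            expected.append(best)
            remaining.remove(best)

        pairs, _ = match_controls(trajs, np.arange(n_pool), pool)
        assert [p.control_start for p in pairs] == expected


class TestAcceleration:
    def test_constant_speed_gives_zero(self):
        assert post_acceleration(np.full(11, 7.0)) == 0.0

    def test_uniform_ramp(self):
        w = np.concatenate([np.full(5, 10.0), np.arange(10.0, 16.0)])
        assert post_acceleration(w) == pytest.approx(30.0)

    @given(hst.lists(hst.floats(-50, 50), min_size=11, max_size=11))
    @settings(max_examples=50, deadline=None)
    def test_telescoping_identity(self, samples):
        w = np.array(samples)
        assert post_acceleration(w) == pytest.approx((w[10] - w[5]) * 30.0 / 5.0, abs=1e-9)


def _pairs_from_diffs(diffs, rng=None):
    rng = rng or np.random.default_rng(0)
    pairs = []
    for i, d in enumerate(diffs):
        ctrl = np.concatenate([np.full(6, 5.0), np.full(5, 5.0)])
        voc = ctrl.copy()
        voc[6:] += np.cumsum(np.full(5, d / 30.0))  # accel == d
        pairs.append(MatchedPair(vocal=_traj(voc, frame=20 + 20 * i),
                                 control=ctrl, control_start=i, match_cost=0.0))
    return pairs


class TestStratumTest:
    def test_identical_pairs_give_null_result(self):
        pairs = _pairs_from_diffs(np.zeros(10))
        res = stratum_test(pairs)
        assert res.t == 0.0 and res.p == 1.0

    def test_constant_offset_is_certain(self):
        res = stratum_test(_pairs_from_diffs(np.full(30, 1.0)))
        assert res.p == 0.0 and res.note == "difference certain"

    def test_too_few_pairs_untestable(self):
        res = stratum_test(_pairs_from_diffs([1.0]))
        assert not res.testable

    def test_power_with_injected_kick(self):
        """kick 1.0 cm/s^2, ~100+ events, accel noise ~0.5 cm/s^2 ->
        significant in >= 95% of 20 seeds."""
        arena = ArenaConfig(duration=200.0)
        beh = BehaviorParams(
            emission_hazard_near=0.012, emission_hazard_far=0.012,
            near_threshold=1000.0,
        )
        hits = 0
        for seed in range(20):
            tracks, truth = simulate_dyad(arena, beh, seed=seed)
            kicked = inject_response_kick(tracks, truth.events, 1.0, 5, arena)
            speeds = np.column_stack(
                [compute_speeds(kicked.centroid[:, m]) for m in (0, 1)]
            )
            dist = np.full(tracks.n_frames, 5.0)  # proximity not under test
            trajs, _ = build_vocal_trajectories(truth.events, speeds, dist)
            frames = [int(e.time * 30.0) for e in truth.events]
            pairs = []
            for voc in (1, 2):
                starts, windows = build_control_pool(speeds[:, 2 - voc], frames)
                sub = [t for t in trajs if t.vocalizer == voc]
                got, _ = match_controls(sub, starts, windows)
                pairs.extend(got)
            res = stratum_test(pairs)
            assert res.n >= 100
            hits += res.p < 0.05 and res.vocal_mean > res.control_mean
        assert hits >= 19


class TestSubsampleNull:
    def test_consistent_difference_detected(self):
        null = subsample_null(_pairs_from_diffs(np.full(20, 1.0)), reps=200, seed=0)
        assert null.p < 1 / 200
        np.testing.assert_allclose(null.means, 1.0)

    def test_symmetric_differences_not_significant(self):
        diffs = np.concatenate([np.linspace(-1, -0.1, 10), np.linspace(0.1, 1, 10)])
        for seed in range(20):
            null = subsample_null(_pairs_from_diffs(diffs), reps=200, seed=seed)
            if null.p < 0.05:
                pytest.fail(f"symmetric null significant at seed {seed}")

    def test_full_subsample_is_degenerate_at_grand_mean(self):
        diffs = np.array([0.5, 1.0, 1.5, 2.0])
        null = subsample_null(_pairs_from_diffs(diffs), m=4, reps=50, seed=1)
        np.testing.assert_allclose(null.means, diffs.mean())

    def test_seed_reproducibility(self):
        diffs = np.random.default_rng(5).normal(0, 1, 30)
        a = subsample_null(_pairs_from_diffs(diffs), reps=300, seed=42)
        b = subsample_null(_pairs_from_diffs(diffs), reps=300, seed=42)
        assert a.p == b.p
        np.testing.assert_array_equal(a.means, b.means)

    def test_oversized_subsample_rejected(self):
        with pytest.raises(ValueError):
            subsample_null(_pairs_from_diffs(np.ones(5)), m=6)


class TestEpochs:
    def test_epoch_boundary_is_half_open(self):
        speeds, dist = _speeds_dist(60000)
        t_just_after = 600.0 + 1.0 / 30.0 + 0.5 / 30.0
        trajs, _ = build_vocal_trajectories([_event(599.9), _event(t_just_after)],
                                            speeds, dist)
        assert trajs[0].epoch == 1
        assert trajs[1].epoch == 2

    def test_controls_stay_inside_their_epoch(self):
        arena = ArenaConfig(duration=1800.0)
        beh = BehaviorParams(emission_hazard_near=0.005, emission_hazard_far=2e-4)
        tracks, truth = simulate_dyad(arena, beh, seed=21)
        speeds = np.column_stack([compute_speeds(tracks.centroid[:, m]) for m in (0, 1)])
        from squeaktrace import interanimal_distance

        dist = interanimal_distance(tracks)
        results = epoch_analysis(truth.events, speeds, dist)
        epoch_frames = int(600 * 30)
        seen_pairs = 0
        for (voc, rel, epoch), (res, pairs) in results.items():
            lo = (epoch - 1) * epoch_frames
            hi = epoch * epoch_frames if epoch < 3 else tracks.n_frames
            for p in pairs:
                assert lo <= p.control_start and p.control_start + 11 <= hi
                assert lo <= p.vocal.emission_frame < hi
                assert p.vocal.isolated
                seen_pairs += 1
        assert seen_pairs > 0

    def test_short_recording_warns_and_bins_proportionally(self):
        speeds, dist = _speeds_dist(900)  # 30 s
        with pytest.warns(UserWarning):
            epoch_analysis([_event(5.0)], speeds, dist)
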
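import numpy as np
import pytest

from larvascreen import (
    BehaviorParams,
    Thresholds,
    WellGeometry,
    activity_pct,
    acoustic_features,
    behavior_vector,
    default_schedule,
    moving_mask,
    occupancy_orientation,
    optomotor_features,
    scoot_burst_pct,
    simulate_track,
)
from larvascreen.errors import ConfigurationError, InsufficientDataError
from larvascreen.features import BEHAVIOR_LABELS
from larvascreen.tracks import LarvaTrack

from conftest import make_track, straight_track

THR = Thresholds()


def _stepped_track(n, moving_frames, step=0.05):
    """Track whose displacement into frame i exceeds the move threshold
    exactly for i in ``moving_frames``; bounded by alternating direction."""
    x = np.zeros(n)
    sign = 1.0
    moving = set(moving_frames)
    for i in range(1, n):
        if i in moving:
            nxt = x[i - 1] + sign * step
            if abs(nxt) > 0.5:
                sign = -sign
                nxt = x[i - 1] + sign * step
            x[i] = nxt
        else:
            x[i] = x[i - 1]
    return make_track(x, np.zeros(n), np.zeros(n))


class TestMovingMask:
    def test_static_track_is_all_false(self):
        track = make_track(np.zeros(10), np.zeros(10), np.zeros(10))
        assert not moving_mask(track, THR.move).any()

    def test_constant_double_threshold_is_all_true(self):
        track = straight_track(10, 2 * THR.move)
        assert moving_mask(track, THR.move).all()

    def test_alternating_fixture_is_exactly_half(self):
        # moving into frames 1,3,...,97 (49 frames); frame 0 inherits
        # frame 1's moving state -> 50 of 100 frames
        track = _stepped_track(100, range(1, 98, 2))
        mask = moving_mask(track, THR.move)
        assert mask.sum() == 50
        assert activity_pct(track, (0.0, 600.0), THR.move) == 50.0

    def test_single_frame_insufficient(self):
        track = make_track([0.0], [0.0], [0.0])
        with pytest.raises(InsufficientDataError):
            moving_mask(track, THR.move)


class TestActivity:
    def test_always_moving_is_100(self):
        track = straight_track(50, 2 * THR.move)
        assert activity_pct(track, (0.0, 300.0), THR.move) == 100.0

    def test_static_is_0(self):
        track = make_track(np.zeros(50), np.zeros(50), np.zeros(50))
        assert activity_pct(track, (0.0, 300.0), THR.move) == 0.0

    def test_hand_counted_fixture(self):
        # moving into frames 2..13 (12 frames); frame 0 inherits frame
        # 1's still state, so exactly 12 of 100 frames count as moving
        track = _stepped_track(100, range(2, 14))
        assert activity_pct(track, (0.0, 600.0), THR.move) == pytest.approx(12.0)

    def test_empty_window_rejected(self):
        track = straight_track(10, 0.05)
        with pytest.raises(InsufficientDataError):
            activity_pct(track, (1000.0, 2000.0), THR.move)


class TestScootBurst:
    def test_all_scoot(self):
        track = straight_track(20, 0.05)  # between move and burst thresholds
        assert scoot_burst_pct(track, (0.0, 120.0), THR) == (100.0, 0.0)

    def test_all_burst(self):
        track = straight_track(20, 0.15)
        assert scoot_burst_pct(track, (0.0, 120.0), THR) == (0.0, 100.0)

    def test_mixed_hand_counted_fixture(self):
        # scoot into frames 2..31 (30), burst into 32..51 (20), rest
        # still; frame 0 inherits frame 1's still state
        x = np.zeros(100)
        sign = 1.0
        for i in range(1, 100):
            if 2 <= i <= 31:
                step = 0.05
            elif 32 <= i <= 51:
                step = 0.15
            else:
                step = 0.0
            nxt = x[i - 1] + sign * step
            if abs(nxt) > 0.5:
                sign = -sign
                nxt = x[i - 1] + sign * step
            x[i] = nxt
        track = make_track(x, np.zeros(100), np.zeros(100))
        sc, bu = scoot_burst_pct(track, (0.0, 600.0), THR)
        assert (sc, bu) == (30.0, 20.0)


class TestOccupancyOrientation:
    def test_pinned_center_fixed_heading(self, well):
        track = make_track(np.zeros(10), np.zeros(10), np.full(10, 45.0))
        ed, cw, orient, turn, tabs = occupancy_orientation(track, (0.0, 60.0), well)
        assert (ed, turn, tabs) == (0.0, 0.0, 0.0)
        assert cw == 0.0

    def test_constant_clockwise_rotation(self, well):
        heading = (np.zeros(20) - 5.0 * np.arange(20)) % 360.0
        track = make_track(np.zeros(20), np.zeros(20), heading)
        _, cw, _, turn, tabs = occupancy_orientation(track, (0.0, 120.0), well)
        assert cw == 100.0
        assert turn == pytest.approx(-5.0)
        assert tabs == pytest.approx(5.0)

    def test_upward_heading(self, well):
        track = make_track(np.zeros(10), np.zeros(10), np.full(10, 90.0))
        _, _, orient, _, _ = occupancy_orientation(track, (0.0, 60.0), well)
        assert orient == 100.0

    def test_edge_occupancy(self):
        well = WellGeometry(radius=1.0, edge_fraction=0.5)
        r = np.concatenate([np.full(25, 0.4), np.full(75, 0.9)])
        track = make_track(r, np.zeros(100), np.zeros(100))
        ed, *_ = occupancy_orientation(track, (0.0, 600.0), well)
        assert ed == 75.0


class TestOptomotor:
    def test_perfect_alignment_scores_plus_50(self, schedule):
        track = straight_track(1800, 0.05, heading_deg=0.0)
        feats = optomotor_features(track, schedule, THR.move)
        for key in ("R", "G", "B", "FR", "RGB"):
            assert feats[key] == pytest.approx(50.0)

    def test_anti_alignment_scores_minus_50(self, schedule):
        track = straight_track(1800, 0.05, heading_deg=180.0)
        feats = optomotor_features(track, schedule, THR.move)
        assert feats["R"] == pytest.approx(-50.0)

    def test_rgb_is_mean_of_r_g_b(self, short_schedule, well):
        params = BehaviorParams(optomotor_gain=0.5)
        track = simulate_track(params, short_schedule, well, seed=21)
        feats = optomotor_features(track, short_schedule, THR.move)
        assert feats["RGB"] == pytest.approx((feats["R"] + feats["G"] + feats["B"]) / 3)

    def test_isotropic_walk_scores_near_zero(self, schedule, well):
        # no optomotor pull, no other directional bias: alignment is a
        # fair coin, so the class scores sit at 0 within Monte-Carlo CI
        params = BehaviorParams(
            optomotor_gain=0.0, edge_attraction=0.0, up_bias=0.0, cw_bias=0.0
        )
        scores = []
        for seed in range(12):
            track = simulate_track(params, schedule, well, seed=seed)
            scores.append(optomotor_features(track, schedule, THR.move)["RGB"])
        mean = np.mean(scores)
        # per-larva sd ~2 points; 12 larvae -> 99% CI about +-1.6
        assert abs(mean) < 2.5

    def test_no_moving_frames_scores_zero_with_warning(self, schedule, caplog):
        track = make_track(np.zeros(1800), np.zeros(1800), np.zeros(1800))
        with caplog.at_level("WARNING"):
            feats = optomotor_features(track, schedule, THR.move)
        assert feats["R"] == 0.0
        assert any("no moving frames" in r.message for r in caplog.records)


class TestAcoustic:
    def test_hand_computed_fixture(self, schedule):
        # activity 20% in period 15, 60% in 16, 30% in 17, 50% in 18
        moving = (
            list(range(1401, 1421))
            + list(range(1501, 1561))
            + list(range(1601, 1631))
            + list(range(1701, 1751))
        )
        track = _stepped_track(1800, moving)
        hab, s, e = acoustic_features(track, schedule, THR.move)
        assert e == pytest.approx(25.0)   # mean(60, 30) - 20
        assert hab == pytest.approx(10.0)  # 30 - 20
        assert s == pytest.approx(30.0)   # 50 - 20

    def test_uniform_activity_gives_zero(self, schedule):
        track = straight_track(1800, 0.05)
        assert acoustic_features(track, schedule, THR.move) == (0.0, 0.0, 0.0)

    def test_static_track_gives_zero(self, schedule):
        track = make_track(np.zeros(1800), np.zeros(1800), np.zeros(1800))
        assert acoustic_features(track, schedule, THR.move) == (0.0, 0.0, 0.0)

    def test_missing_required_period_is_config_error(self):
        from larvascreen.protocol import Period, StimulusSchedule

        periods = (
            Period(1, 0.0, 10.0, "rest"),
            Period(2, 10.0, 20.0, "acoustic", isi_s=1),
        )
        schedule = StimulusSchedule(periods, 20.0)
        track = straight_track(200, 0.05)
        with pytest.raises(ConfigurationError):
            acoustic_features(track, schedule, THR.move)


class TestBehaviorVector:
    def test_labels_fixed_order(self, short_schedule, well, base_params):
        track = simulate_track(base_params, short_schedule, well, seed=2)
        vec = behavior_vector(track, short_schedule, well)
        assert tuple(vec.index) == BEHAVIOR_LABELS

    def test_invariants(self, short_schedule, well, base_params):
        track = simulate_track(base_params, short_schedule, well, seed=2)
        vec = behavior_vector(track, short_schedule, well)
        percent = ["act_1h", "P15", "Sc_1h", "Sc_V", "Bu_1h", "Bu_V",
                   "Ed_1h", "Ed_V", "Cw_1h", "Cw_V", "Or"]
        assert ((vec[percent] >= 0) & (vec[percent] <= 100)).all()
        assert vec["RGB"] == pytest.approx((vec["R"] + vec["G"] + vec["B"]) / 3)
        assert vec["Tabs_1h"] >= abs(vec["Turn_1h"])
        # scoot + burst partition the moving frames of the same window
        hour = (0.0, 3600.0)
        assert vec["Sc_1h"] + vec["Bu_1h"] == pytest.approx(
            activity_pct(track, hour, THR.move)
        )

    def test_deterministic(self, short_schedule, well, base_params):
        track = simulate_track(base_params, short_schedule, well, seed=2)
        a = behavior_vector(track, short_schedule, well)
        b = behavior_vector(track, short_schedule, well)
        assert (a == b).all()


class TestSymmetries:
    def _rotate(self, track, phi):
        rad = np.radians(phi)
        x = track.x * np.cos(rad) - track.y * np.sin(rad)
        y = track.x * np.sin(rad) + track.y * np.cos(rad)
        return LarvaTrack(track.arm_id, track.well_id, track.t_s, x, y,
                          (track.heading_deg + phi) % 360.0)

    def test_rotation_equivariance_of_optomotor(self, well, base_params):
        phi = 37.0
        schedule = default_schedule(period_min=1.0)
        rotated_schedule = default_schedule(motion_direction_deg=phi, period_min=1.0)
        track = simulate_track(base_params, schedule, well, seed=13)
        rotated = self._rotate(track, phi)
        a = optomotor_features(track, schedule, THR.move)
        b = optomotor_features(rotated, rotated_schedule, THR.move)
        for key in a:
            assert b[key] == pytest.approx(a[key], abs=1e-9)

    def test_rotation_preserves_turning_and_flips_orientation(
        self, short_schedule, well, base_params
    ):
        track = simulate_track(base_params, short_schedule, well, seed=13)
        rotated = self._rotate(track, 180.0)
        full = (0.0, short_schedule.total_duration_min * 60.0)
        ed_a, cw_a, or_a, turn_a, tabs_a = occupancy_orientation(track, full, well)
        ed_b, cw_b, or_b, turn_b, tabs_b = occupancy_orientation(rotated, full, well)
        assert (ed_b, cw_b) == (ed_a, cw_a)
        assert turn_b == pytest.approx(turn_a, abs=1e-9)
        assert tabs_b == pytest.approx(tabs_a, abs=1e-9)
        assert or_b == pytest.approx(100.0 - or_a, abs=1e-9)

    def test_time_reversal_flips_turn_preserves_tabs(
        self, short_schedule, well, base_params
    ):
        track = simulate_track(base_params, short_schedule, well, seed=14)
        reversed_track = LarvaTrack(
            track.arm_id, track.well_id, track.t_s,
            track.x[::-1], track.y[::-1], track.heading_deg[::-1],
        )
        full = (0.0, short_schedule.total_duration_min * 60.0)
        *_, turn_a, tabs_a = occupancy_orientation(track, full, well)
        *_, turn_b, tabs_b = occupancy_orientation(reversed_track, full, well)
        assert turn_b == pytest.approx(-turn_a, abs=1e-12)
        assert tabs_b == pytest.approx(tabs_a, abs=1e-12)
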
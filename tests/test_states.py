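"""Hysteresis movement state, mobility classification, multi-conditions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import (
    add_pulse,
    hysteresis_oracle,
    make_series,
    mobility_oracle,
    stationary_center,
)
from myotrack.core_io import Signal
from myotrack.states import (
    BodyPointsMissingError,
    DetectionConfig,
    Mobility,
    compute_profile,
    mobility_raw,
    mobility_state,
    movement_state,
    multi_condition_1,
    multi_condition_2,
)


class TestMovementState:
    def test_constant_zero_velocity_never_moving(self):
        out = movement_state(np.zeros(50), 3.20, 2.25)
        assert not out.values.any()

    def test_constant_fast_velocity_moving_from_first_sample(self):
        out = movement_state(np.full(50, 10.0), 3.20, 2.25)
        assert out.values.all()

    def test_hand_stepped_hysteresis_sequence(self):
        v = np.array([1.0, 4.0, 3.0, 2.0, 1.0])
        out = movement_state(v, 3.20, 2.25)
        assert list(out.values) == [False, True, True, False, False]

    def test_stop_threshold_must_be_below_start(self):
        with pytest.raises(ValueError):
            movement_state(np.zeros(5), 2.0, 2.0)

    def test_missing_velocity_holds_state(self):
        v = np.array([5.0, np.nan, np.nan, 1.0, np.nan])
        out = movement_state(v, 3.20, 2.25)
        assert list(out.values) == [True, True, True, False, False]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0, 6, size=200)
        v[rng.uniform(size=200) < 0.1] = np.nan
        out = movement_state(v, 3.20, 2.25).values
        np.testing.assert_array_equal(out, hysteresis_oracle(v, 3.20, 2.25))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(10, 150))
    def test_causality_prefix_property(self, seed, cut):
        """State at sample i depends only on samples <= i."""
        rng = np.random.default_rng(seed)
        v = rng.uniform(0, 6, size=200)
        full = movement_state(v, 3.20, 2.25).values
        prefix = movement_state(v[:cut], 3.20, 2.25).values
        np.testing.assert_array_equal(full[:cut], prefix)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 3.0))
    def test_raising_thresholds_never_adds_moving_samples(self, seed, bump):
        rng = np.random.default_rng(seed)
        v = rng.uniform(0, 8, size=300)
        base = movement_state(v, 3.20, 2.25).values.sum()
        raised = movement_state(v, 3.20 + bump, 2.25 + bump).values.sum()
        assert raised <= base


class TestMobility:
    def test_perfectly_still_gives_zero(self):
        s = make_series(stationary_center(30))
        assert mobility_raw(s).values.max() == 0.0

    def test_body_length_displacement_gives_ninety_percent(self):
        # all three points displace exactly L per sample, constant posture:
        # 100 * min(1, (0.3+0.3+0.3)*1 + 0) = 90
        cfg = DetectionConfig()
        L = cfg.body_length_cm
        c = np.cumsum(np.tile([L, 0.0], (10, 1)), axis=0)
        s = make_series(c, nose=c + [2, 0], tail=c - [2, 0], arena=1e9)
        m = mobility_raw(s, cfg)
        np.testing.assert_allclose(m.values[1:], 90.0, rtol=1e-12)

    def test_matches_formula_oracle(self, rng):
        c = np.cumsum(rng.normal(0, 0.3, (80, 2)), axis=0) + 15
        s = make_series(c, nose=c + rng.normal(0, 0.5, (80, 2)),
                        tail=c - rng.normal(0, 0.5, (80, 2)),
                        elongation=rng.uniform(40, 95, 80))
        cfg = DetectionConfig()
        np.testing.assert_allclose(mobility_raw(s, cfg).values,
                                   mobility_oracle(s, cfg), rtol=1e-9)

    @pytest.mark.parametrize("pct,expected", [
        (0.0, Mobility.IMMOBILE),
        (30.0, Mobility.MOBILE),
        (70.0, Mobility.HIGHLY_MOBILE),
    ])
    def test_constant_mobility_thresholds(self, pct, expected):
        cfg = DetectionConfig()
        out = mobility_state(Signal(np.full(60, pct), "%"), cfg)
        assert (out.values == expected).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_labels_partition_every_sample(self, seed):
        rng = np.random.default_rng(seed)
        m = Signal(rng.uniform(0, 100, 200), "%")
        out = mobility_state(m, DetectionConfig()).values
        assert np.isin(out, [Mobility.IMMOBILE, Mobility.MOBILE,
                             Mobility.HIGHLY_MOBILE]).all()


def _spike_series(n=300, elongation=70.0, angle=10.0, spike=True):
    """Stationary series with one small displacement step (v = 5 cm/s)."""
    c = stationary_center(n)
    if spike:
        c[150:] += [0.2, 0.0]  # 0.2 cm step -> 5 cm/s for one sample
    return make_series(c, elongation=elongation, angle=angle)


class TestMultiConditions:
    def test_mc1_true_for_spike_in_quiescence(self):
        s = _spike_series()
        out = multi_condition_1(s, DetectionConfig())
        assert out.values[150]
        # (100-sample mean velocity = 5/100 = 0.05 <= 0.45; elong 70 <= 75;
        # angle 10 <= 20; hysteresis Moving at the spike sample)

    def test_mc1_false_when_elongation_exceeds_bound(self):
        out = multi_condition_1(_spike_series(elongation=80.0), DetectionConfig())
        assert not out.values.any()

    def test_mc1_false_without_movement(self):
        out = multi_condition_1(_spike_series(spike=False), DetectionConfig())
        assert not out.values.any()

    def test_mc1_relaxing_bounds_is_monotone(self, rng):
        c = np.cumsum(rng.normal(0, 0.05, (400, 2)), axis=0) + 15
        s = make_series(c, elongation=rng.uniform(60, 90, 400),
                        angle=rng.uniform(0, 40, 400))
        tight = multi_condition_1(s, DetectionConfig()).values
        loose = multi_condition_1(s, DetectionConfig(
            mc1_avg_vel_max_cms=1.0, mc1_elong_max_pct=95.0,
            mc1_angle_max_deg=60.0)).values
        assert (tight <= loose).all()

    def _three_point_walk(self, accel_spike=False, nose_still=False):
        n = 200
        step = 5.0 / 25.0  # 5 cm/s
        c = np.zeros((n, 2)) + [5.0, 15.0]
        c[:, 0] += np.arange(n) * step
        if accel_spike:
            c[100:, 0] += 8.0 / 25.0  # one-sample velocity jump of 8 cm/s
        nose = np.tile([15.0, 10.0], (n, 1)) if nose_still else c + [2, 0]
        return make_series(c, nose=nose, tail=c - [2, 0], arena=1e9)

    def test_mc2_true_when_all_points_move_gently(self):
        out = multi_condition_2(self._three_point_walk(), DetectionConfig())
        assert out.values[1:].all()

    def test_mc2_false_at_acceleration_spike(self):
        out = multi_condition_2(self._three_point_walk(accel_spike=True),
                                DetectionConfig())
        assert not out.values[100]          # |dv| * 25 = 200 > 180
        assert out.values[99] and out.values[102]

    def test_mc2_false_when_nose_still(self):
        out = multi_condition_2(self._three_point_walk(nose_still=True),
                                DetectionConfig())
        assert not out.values.any()

    def test_mc2_missing_nose_raises_fallback_error(self):
        s = _spike_series()
        s.nose_xy[:] = np.nan
        with pytest.raises(BodyPointsMissingError, match="trajectory-only"):
            multi_condition_2(s, DetectionConfig())

    def test_profile_disables_mc2_when_nose_missing(self):
        s = _spike_series()
        s.nose_xy[:] = np.nan
        s.missing = np.zeros(len(s), bool)
        prof = compute_profile(s, DetectionConfig())
        assert not prof.mc2_available
        assert not prof.mc2.values.any()


class TestDetectionConfig:
    def test_defaults_are_published_profile(self):
        cfg = DetectionConfig()
        assert (cfg.move_start_cms, cfg.move_stop_cms) == (3.20, 2.25)
        assert cfg.mc1_avg_vel_max_cms == 0.45
        assert cfg.mc2_accel_max_cms2 == 180.00
        assert (cfg.mobility_high_pct, cfg.mobility_immobile_pct) == (60.0, 5.0)

    @pytest.mark.parametrize("kwargs", [
        {"move_stop_cms": 4.0},
        {"mc2_move_stop_cms": 2.5},
        {"mobility_immobile_pct": 70.0},
        {"burst_vel_min_cms": 80.0},
        {"analysis_start_s": 20000.0},
        {"mobility_window_samples": 0},
    ])
    def test_invariant_violations_raise(self, kwargs):
        with pytest.raises(ValueError):
            DetectionConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        cfg = DetectionConfig(burst_max_dur_s=2.0, pre_immobile_min_s=5.0)
        p = tmp_path / "det.yaml"
        cfg.to_yaml(p)
        assert DetectionConfig.from_yaml(p) == cfg

    def test_unknown_yaml_key_rejected(self, tmp_path):
        p = tmp_path / "det.yaml"
        p.write_text("move_start_cms: 3.2\nbanana: 1\n")
        with pytest.raises(ValueError, match="banana"):
            DetectionConfig.from_yaml(p)
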
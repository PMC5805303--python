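"""Filtering, speed profiles, onset/offset criteria, and trial measures."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import signal

import dualadapt as da
from dualadapt.kinematics import (
    FilterSpec,
    analyze_trial,
    angular_error_at_peak_velocity,
    lowpass_filter,
    movement_offset,
    movement_onset,
    pursuit_descriptors,
    speed_profile,
    tracking_rmse,
    wrap_angle_deg,
)
from dualadapt.paradigm import Phase
from dualadapt.simulator import LearnerState, NoiseParams, simulate_track_trial


def _first_order_butter_coefficients(fc: float, fs: float):
    """Closed-form bilinear-transform coefficients for a 1st-order lowpass."""
    k = np.tan(np.pi * fc / fs)
    b0 = k / (k + 1.0)
    a1 = (k - 1.0) / (k + 1.0)
    return np.array([b0, b0]), np.array([1.0, a1])


def test_filter_preserves_constants():
    series = np.full((50, 2), 3.25)
    for zero_phase in (True, False):
        out = lowpass_filter(series, FilterSpec(zero_phase=zero_phase))
        np.testing.assert_allclose(out, series, atol=1e-9)


def test_filter_translation_equivariance(rng):
    series = rng.normal(size=(80, 2))
    shift = np.array([5.0, -2.0])
    a = lowpass_filter(series + shift)
    b = lowpass_filter(series) + shift
    np.testing.assert_allclose(a, b, atol=1e-9)


def test_filter_gain_at_cutoff():
    """First-order transfer function: |H| = 1/sqrt(2) at fc (1/2 zero-phase)."""
    fs, fc = 50.0, 2.5
    t = np.arange(0, 40, 1 / fs)
    x = np.sin(2 * np.pi * fc * t)
    mid = slice(len(t) // 4, 3 * len(t) // 4)
    single = lowpass_filter(np.c_[x, x], FilterSpec(zero_phase=False))[mid, 0]
    double = lowpass_filter(np.c_[x, x], FilterSpec(zero_phase=True))[mid, 0]
    assert np.max(np.abs(single)) == pytest.approx(1 / np.sqrt(2), rel=0.02)
    assert np.max(np.abs(double)) == pytest.approx(0.5, rel=0.02)


def test_filter_impulse_response_matches_coefficient_oracle():
    b_ref, a_ref = _first_order_butter_coefficients(2.5, 50.0)
    b, a = signal.butter(1, 2.5, fs=50.0)
    np.testing.assert_allclose(b, b_ref, atol=1e-12)
    np.testing.assert_allclose(a, a_ref, atol=1e-12)
    impulse = np.zeros((32, 1))
    impulse[0] = 1.0
    out = lowpass_filter(impulse, FilterSpec(zero_phase=False))[:, 0]
    # direct-form recursion oracle with DC steady-state initialization at the
    # first sample (x[-1] = y[-1] = x[0])
    x0 = impulse[0, 0]
    ref = np.zeros(32)
    ref[0] = b_ref[0] * impulse[0, 0] + b_ref[1] * x0 - a_ref[1] * x0
    for n in range(1, 32):
        ref[n] = b_ref[0] * impulse[n, 0] + b_ref[1] * impulse[n - 1, 0] - a_ref[1] * ref[n - 1]
    np.testing.assert_allclose(out, ref, atol=1e-12)


def test_filter_input_validation():
    with pytest.raises(ValueError):
        lowpass_filter(np.zeros((3, 2)))
    with pytest.raises(ValueError):
        FilterSpec(cutoff_hz=25.0)


def test_speed_profile_cases():
    static = np.tile([1.0, 2.0], (20, 1))
    np.testing.assert_allclose(speed_profile(static, 50.0), 0.0, atol=1e-12)
    t = np.arange(30) / 50.0
    ramp = np.c_[3.0 * t, 4.0 * t]  # |v| = 5 exactly
    np.testing.assert_allclose(speed_profile(ramp, 50.0), 5.0, atol=1e-9)
    with pytest.raises(ValueError):
        speed_profile(ramp[:2], 50.0)


def test_target_speed_is_eight(mini_designs):
    spec = [
        t for t in da.build_session("SINGLE_TRACK", 0).trials
        if t.phase is Phase.ROTATED_TRAIN
    ][0]
    _, xy = da.target_path(spec, fs_hz=50.0)
    sp = speed_profile(xy, 50.0)
    np.testing.assert_allclose(sp[1:-1], 8.0, rtol=1e-9)


def _oracle_onset(speed, fraction):
    """Exhaustive scan: latest below-threshold sample before the peak, +1."""
    peak = int(np.argmax(speed))
    thr = fraction * speed[peak]
    below = [j for j in range(peak) if speed[j] < thr]
    return below[-1] + 1 if below else 0


def _oracle_offset(speed, fraction):
    peak = int(np.argmax(speed))
    thr = fraction * speed[peak]
    after = [k for k in range(peak + 1, len(speed)) if speed[k] < thr]
    return (after[0] - 1, False) if after else (len(speed) - 1, True)


def test_onset_threshold_example():
    speed = np.concatenate([np.arange(11.0), [9.0, 5.0, 1.0]])
    assert movement_onset(speed, 0.33) == 4  # first sample >= 3.3
    assert movement_onset(speed, 0.10) <= movement_onset(speed, 0.33)


@given(st.lists(st.floats(0.0, 100.0), min_size=5, max_size=60), st.sampled_from([0.10, 0.33]))
def test_onset_offset_match_exhaustive_oracle(values, fraction):
    speed = np.asarray(values)
    if speed.max() <= 0:
        with pytest.raises(ValueError):
            movement_onset(speed, fraction)
        return
    assert movement_onset(speed, fraction) == _oracle_onset(speed, fraction)
    assert movement_offset(speed, fraction) == _oracle_offset(speed, fraction)


def test_offset_symmetric_triangle_and_flat_tail():
    tri = np.concatenate([np.arange(11.0), np.arange(11.0)[::-1][1:]])
    onset = movement_onset(tri, 0.33)
    offset, clipped = movement_offset(tri, 0.33)
    assert not clipped
    assert offset == len(tri) - 1 - onset
    flat = np.concatenate([np.arange(11.0), np.full(5, 10.0)])
    offset, clipped = movement_offset(flat, 0.33)
    assert clipped and offset == len(flat) - 1


def test_angular_error_examples():
    home = np.zeros(2)

    def ray(angle, r=10.0):
        a = np.deg2rad(angle)
        return r * np.array([np.cos(a), np.sin(a)])

    cursor = np.linspace(0, 1, 20)[:, None] * ray(105.0)
    target = ray(90.0)
    err = angular_error_at_peak_velocity(cursor, target, home)
    assert err == pytest.approx(15.0, abs=1e-9)
    aligned = angular_error_at_peak_velocity(np.linspace(0, 1, 20)[:, None] * ray(90.0), target, home)
    assert aligned == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError):
        angular_error_at_peak_velocity(np.zeros((20, 2)), target, home)


def test_angular_error_scene_invariance(rng):
    """Invariant to uniform scaling and whole-scene rotation."""
    cursor = np.linspace(0, 1, 25)[:, None] * np.array([3.0, 7.0])
    target = np.array([1.0, 9.0])
    base = angular_error_at_peak_velocity(cursor, target)
    scaled = angular_error_at_peak_velocity(2.7 * cursor, 2.7 * target)
    rot = da.simulator.rotate_about
    turned = angular_error_at_peak_velocity(
        rot(cursor, 37.0, (0, 0)), rot(target[None], 37.0, (0, 0))[0]
    )
    assert scaled == pytest.approx(base, abs=1e-9)
    assert turned == pytest.approx(base, abs=1e-9)


def test_wrap_angle_convention():
    assert wrap_angle_deg(180.0) == 180.0
    assert wrap_angle_deg(-180.0) == 180.0
    assert wrap_angle_deg(190.0) == pytest.approx(-170.0)
    np.testing.assert_allclose(wrap_angle_deg(np.array([360.0, -90.0])), [0.0, -90.0])


def test_rmse_examples():
    a = np.zeros((3, 2))
    assert tracking_rmse(a, a) == 0.0
    offset = a + np.array([0.0, 3.0])
    assert tracking_rmse(a, offset) == pytest.approx(3.0)
    cursor = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 4.0]])
    assert tracking_rmse(cursor, np.zeros((3, 2))) == pytest.approx(np.sqrt(25.0 / 3.0))
    with pytest.raises(ValueError):
        tracking_rmse(a, a[:2])


@given(
    st.integers(1, 40),
    st.integers(0, 2**31 - 1),
)
def test_rmse_matches_brute_force_oracle(n, seed):
    r = np.random.default_rng(seed)
    cursor = r.normal(size=(n, 2)) * 10
    target = r.normal(size=(n, 2)) * 10
    acc = 0.0
    for i in range(n):
        dx = cursor[i, 0] - target[i, 0]
        dy = cursor[i, 1] - target[i, 1]
        acc += dx * dx + dy * dy
    assert tracking_rmse(cursor, target) == pytest.approx(np.sqrt(acc / n), rel=1e-12)


def test_pursuit_descriptors_lockstep():
    spec = [
        t for t in da.build_session("SINGLE_TRACK", 0).trials if t.phase is Phase.ROTATED_TRAIN
    ][0]
    t_ms, xy = da.target_path(spec, fs_hz=50.0)
    latency, dist, mt = pursuit_descriptors(t_ms, xy, xy, 50.0)
    assert latency == 0.0
    assert dist == 0.0
    assert mt > 0


def test_pursuit_latency_recovers_programmed_lag(default_learner):
    """With a fast controller, onset latency equals the pursuit lag +/- 1 sample."""
    spec = [
        t for t in da.build_session("SINGLE_TRACK", 0).trials if t.phase is Phase.ROTATED_TRAIN
    ][0]
    noise = NoiseParams(aim_sd_deg=0.0, pursuit_lag_ms=400.0, pursuit_gain_per_s=40.0, seed=0)
    traj = simulate_track_trial(spec, LearnerState(z_shared=-30.0), default_learner, noise)
    m = analyze_trial(traj)
    assert abs(m.pursuit_latency_ms - 400.0) <= 20.0
    assert m.onset_distance_cm == pytest.approx(0.4 * 8.0, abs=0.5)


def test_converged_tracking_movement_time(default_learner, noiseless_noise):
    """Default controller: onset-to-offset time on a converged tracking trial."""
    spec = [
        t for t in da.build_session("SINGLE_TRACK", 0).trials if t.phase is Phase.ROTATED_TRAIN
    ][0]
    traj = simulate_track_trial(spec, LearnerState(z_shared=-30.0), default_learner, noiseless_noise)
    m = analyze_trial(traj)
    assert 1200.0 <= m.movement_time_ms <= 2000.0


def test_analyze_trial_unadapted_rotated_reach(noiseless_noise, default_learner):
    """Full pipeline on a noise-free unadapted reach under -30: error = -30."""
    design = da.build_session("SINGLE_REACH", 0)
    spec = [t for t in design.trials if t.phase is Phase.ROTATED_TRAIN][0]
    traj = da.simulate_reach_trial(spec, LearnerState(), default_learner, noiseless_noise)
    m = analyze_trial(traj)
    assert m.angular_error_deg == pytest.approx(-30.0, abs=1e-9)
    assert m.onset_index <= m.offset_index
    assert m.peak_speed_cm_s > 0
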
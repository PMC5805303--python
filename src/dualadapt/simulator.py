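"""Synthetic session generator: a contextual state-space motor learner.

The generator produces 50 Hz planar hand/cursor/target trajectories for whole
sessions. Trial-to-trial adaptation follows a state-space rule with one state
shared across movement types and one state per context (reach, track):

    z_shared  <-  A * z_shared  - B_s * e
    z_context <-  A * z_context - B_c * e        (trained context)
    z_other   <-  A * z_other                    (untrained context decays)

where ``A`` is retention, ``B_s``/``B_c`` are learning rates, and ``e`` is the
trial's signed angular error (deg, CCW-positive). The compensation expressed
in a context is ``z_shared + z_context``; at the noiseless single-context
fixed point it equals ``-rotation * B / (1 - A + B)`` with ``B = B_s + B_c``.

Reaches are ballistic minimum-jerk strokes aimed at the target direction plus
the current compensation (plus Gaussian aiming noise); the error signal is the
cursor-target angle at peak velocity. Tracking is a first-order proportional
pursuit of the (lagged) target, steered through the compensation angle; its
error signal is the mean signed cursor-target angle from cursor-motion onset
until the target halts. No-cursor reaches neither update nor decay the states.

Default learner parameters were calibrated by noiseless simulation sweeps so
that reach-only training asymptotes near 19 deg of the 30 deg rotation, about
half of it transfers from tracking training (~9 deg, opposite rotation), and
dual training leaves a residual reach aftereffect of ~7 deg.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

from . import kinematics
from .paradigm import (
    MovementType,
    SessionCounts,
    SessionDesign,
    TargetGeometry,
    TrialSpec,
    build_session,
    target_path,
)

__all__ = [
    "LearnerParams",
    "LearnerState",
    "NoiseParams",
    "Trajectory",
    "calibrate_defaults",
    "update_learner",
    "simulate_reach_trial",
    "simulate_track_trial",
    "simulate_session",
    "simulate_group",
    "hidden_state_table",
    "rotate_about",
]

FS_HZ = 50.0
TRACK_TIME_CAP_MS = 3000.0


@dataclass(frozen=True)
class LearnerParams:
    """State-space learner parameters.

    retention
        Per-trial decay factor ``A`` in (0, 1], applied to every state on
        each feedback trial.
    rate_shared, rate_context
        Learning rates for the shared and the context-specific state.
    track_error_weight
        Scalar mapping the tracking-trial error signal onto the update.
    """

    retention: float = 0.97
    rate_shared: float = 0.0238
    rate_context: float = 0.0202
    track_error_weight: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.retention <= 1:
            raise ValueError("retention must lie in (0, 1]")
        if self.rate_shared < 0 or self.rate_context < 0:
            raise ValueError("learning rates must be non-negative")
        if self.rate_shared + self.rate_context >= 1:
            raise ValueError("combined learning rate must stay below 1")


def calibrate_defaults() -> LearnerParams:
    """Package default learner parameters (see module docstring)."""
    return LearnerParams()


@dataclass(frozen=True)
class LearnerState:
    """Hidden adaptation states (deg). All zero at session start."""

    z_shared: float = 0.0
    z_reach: float = 0.0
    z_track: float = 0.0

    def compensation(self, context: str) -> float:
        """Total compensation expressed in a movement context."""
        if context == "reach":
            return self.z_shared + self.z_reach
        if context == "track":
            return self.z_shared + self.z_track
        raise ValueError(f"unknown context {context!r}")


@dataclass(frozen=True)
class NoiseParams:
    """Execution parameters of the simulated participant.

    aim_sd_deg
        SD of per-trial Gaussian aiming noise (deg).
    reach_duration_ms
        Duration of the ballistic reach stroke.
    pursuit_lag_ms
        First-order pursuit delay behind the target.
    pursuit_gain_per_s
        Proportional pursuit controller gain (1/s).
    """

    aim_sd_deg: float = 3.5
    reach_duration_ms: float = 1000.0
    pursuit_lag_ms: float = 400.0
    pursuit_gain_per_s: float = 6.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.aim_sd_deg < 0:
            raise ValueError("aim noise SD must be non-negative")
        if min(self.reach_duration_ms, self.pursuit_lag_ms, self.pursuit_gain_per_s) <= 0:
            if self.reach_duration_ms <= 0 or self.pursuit_gain_per_s <= 0:
                raise ValueError("durations and gain must be positive")
        if self.pursuit_lag_ms < 0:
            raise ValueError("pursuit lag must be non-negative")


@dataclass
class Trajectory:
    """Time-stamped hand/cursor/target positions for one trial.

    ``cursor_xy_cm`` is None on no-cursor trials. ``hidden_state`` is the
    learner state snapshot *after* the trial.
    """

    t_ms: np.ndarray
    hand_xy_cm: np.ndarray
    cursor_xy_cm: np.ndarray | None
    target_xy_cm: np.ndarray
    spec: TrialSpec
    hidden_state: LearnerState


def rotate_about(points: np.ndarray, angle_deg: float, about) -> np.ndarray:
    """Rotate planar points CCW by ``angle_deg`` about a pivot."""
    a = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    about = np.asarray(about, dtype=float)
    return (np.asarray(points, dtype=float) - about) @ rot.T + about


def update_learner(
    state: LearnerState, context: str, error_deg: float, params: LearnerParams
) -> LearnerState:
    """One state-space update driven by a signed error from ``context``."""
    if not np.isfinite(error_deg):
        raise ValueError("error must be finite")
    a, bs, bc = params.retention, params.rate_shared, params.rate_context
    z_shared = a * state.z_shared - bs * error_deg
    if context == "reach":
        return LearnerState(z_shared, a * state.z_reach - bc * error_deg, a * state.z_track)
    if context == "track":
        return LearnerState(z_shared, a * state.z_reach, a * state.z_track - bc * error_deg)
    raise ValueError(f"unknown context {context!r}")


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def simulate_reach_trial(
    spec: TrialSpec,
    state: LearnerState,
    lp: LearnerParams,
    noise: NoiseParams,
    rng: np.random.Generator | None = None,
    geometry: TargetGeometry | None = None,
    fs_hz: float = FS_HZ,
) -> Trajectory:
    """Ballistic reach (or open-loop no-cursor reach) toward a static target.

    The hand travels 12 cm along ``target direction + compensation + noise``
    with a minimum-jerk speed profile. On cursor-visible trials the learner
    is updated with the cursor-target angular error at peak velocity.
    """
    if spec.movement_type is MovementType.TRACK:
        raise ValueError("simulate_reach_trial requires a REACH or NOCURSOR spec")
    geometry = geometry or TargetGeometry()
    rng = rng or np.random.default_rng(noise.seed)
    home = np.asarray(geometry.home_cm, dtype=float)

    aim_noise = rng.normal(0.0, noise.aim_sd_deg) if noise.aim_sd_deg > 0 else 0.0
    heading = spec.target_angle_deg + state.compensation("reach") + aim_noise
    t_ms, target_xy = target_path(spec, geometry, fs_hz, duration_ms=noise.reach_duration_ms)
    tau = t_ms / noise.reach_duration_ms
    radius = geometry.target_radius_cm * _minimum_jerk(np.clip(tau, 0.0, 1.0))
    u = np.array([np.cos(np.deg2rad(heading)), np.sin(np.deg2rad(heading))])
    hand = home + radius[:, None] * u

    cursor = rotate_about(hand, spec.rotation_deg, home) if spec.cursor_visible else None
    new_state = state
    if spec.cursor_visible:
        peak = int(np.argmax(kinematics.speed_profile(cursor, fs_hz)))
        error = kinematics.angular_error_at_peak_velocity(
            cursor, target_xy[-1], home, peak_index=peak
        )
        new_state = update_learner(state, "reach", error, lp)
    return Trajectory(t_ms, hand, cursor, target_xy, spec, new_state)


def simulate_track_trial(
    spec: TrialSpec,
    state: LearnerState,
    lp: LearnerParams,
    noise: NoiseParams,
    rng: np.random.Generator | None = None,
    geometry: TargetGeometry | None = None,
    fs_hz: float = FS_HZ,
) -> Trajectory:
    """Pursuit of a constant-speed radial target under a rotated cursor.

    The hand obeys a first-order proportional pursuit law toward a goal: the
    target position ``pursuit_lag_ms`` earlier, rotated about home by the
    current compensation (plus aiming noise). The cursor is the rotated hand,
    so its residual misalignment from the target is ``rotation +
    compensation`` and vanishes as compensation approaches ``-rotation``.
    The trial runs past the target halt until the cursor overlaps the target,
    up to a 3 s cap. The learner is updated with the mean signed
    cursor-target angle from cursor-motion onset until target halt, scaled by
    ``track_error_weight``.
    """
    if spec.movement_type is not MovementType.TRACK:
        raise ValueError("simulate_track_trial requires a TRACK spec")
    geometry = geometry or TargetGeometry()
    rng = rng or np.random.default_rng(noise.seed)
    home = np.asarray(geometry.home_cm, dtype=float)
    dur = float(spec.target_duration_ms)

    aim_noise = rng.normal(0.0, noise.aim_sd_deg) if noise.aim_sd_deg > 0 else 0.0
    comp = state.compensation("track") + aim_noise

    dt_ms = 1000.0 / fs_hz
    n = int(np.floor(TRACK_TIME_CAP_MS / dt_ms)) + 1
    t_ms = np.arange(n) * dt_ms
    final = geometry.target_position(spec.target_angle_deg)
    frac = np.clip(t_ms / dur, 0.0, 1.0)[:, None]
    target_xy = home + frac * (final - home)

    lag_frac = np.clip((t_ms - noise.pursuit_lag_ms) / dur, 0.0, 1.0)[:, None]
    goal = rotate_about(home + lag_frac * (final - home), comp, home)

    # First-order pursuit hand' = gain * (goal - hand) integrated by forward
    # Euler at the sampling step; equivalent to a one-pole IIR filter.
    alpha = noise.pursuit_gain_per_s * (dt_ms / 1000.0)
    if not 0 < alpha < 1:
        raise ValueError("pursuit gain times sampling step must lie in (0, 1)")
    hand = home + _signal.lfilter([0.0, alpha], [1.0, alpha - 1.0], goal - home, axis=0)
    cursor = rotate_about(hand, spec.rotation_deg, home)

    halt = int(np.searchsorted(t_ms, dur))
    dist = np.hypot(*(cursor - target_xy).T)
    captured = np.flatnonzero(dist[halt:] <= geometry.overlap_threshold_cm)
    end = halt + int(captured[0]) if captured.size else n - 1

    t_ms, hand, cursor, target_xy = (
        t_ms[: end + 1],
        hand[: end + 1],
        cursor[: end + 1],
        target_xy[: end + 1],
    )

    speed = kinematics.speed_profile(cursor, fs_hz)
    onset = kinematics.movement_onset(speed, kinematics.TRACK_ONSET_FRACTION)
    window = slice(max(onset, 1), min(halt, end) + 1)
    c = cursor[window] - home
    g = target_xy[window] - home
    ang = np.degrees(np.arctan2(c[:, 1], c[:, 0]) - np.arctan2(g[:, 1], g[:, 0]))
    error = float(np.mean(kinematics.wrap_angle_deg(ang)))
    new_state = update_learner(state, "track", lp.track_error_weight * error, lp)
    return Trajectory(t_ms, hand, cursor, target_xy, spec, new_state)


def simulate_session(
    design: SessionDesign,
    lp: LearnerParams | None = None,
    noise: NoiseParams | None = None,
    geometry: TargetGeometry | None = None,
    fs_hz: float = FS_HZ,
) -> list[Trajectory]:
    """Simulate every trial of a session in order; reproducible from seed.

    Hidden states evolve only on cursor-visible trials; no-cursor reaches
    leave them untouched.
    """
    lp = lp or calibrate_defaults()
    noise = noise or NoiseParams()
    geometry = geometry or TargetGeometry()
    rng = np.random.default_rng(noise.seed)
    state = LearnerState()
    out: list[Trajectory] = []
    for spec in design.trials:
        if spec.movement_type is MovementType.TRACK:
            traj = simulate_track_trial(spec, state, lp, noise, rng, geometry, fs_hz)
        else:
            traj = simulate_reach_trial(spec, state, lp, noise, rng, geometry, fs_hz)
        state = traj.hidden_state
        out.append(traj)
    return out


def simulate_group(
    design_name: str,
    n_participants: int,
    lp: LearnerParams | None = None,
    noise: NoiseParams | None = None,
    seed: int = 0,
    counts: SessionCounts | None = None,
) -> list[tuple[SessionDesign, list[Trajectory]]]:
    """Simulate a group of participants with independent schedules and noise.

    Per-participant seeds are spawned deterministically from ``seed``.
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    noise = noise or NoiseParams()
    out = []
    for child in np.random.SeedSequence(seed).spawn(n_participants):
        s_schedule, s_noise = (int(v) for v in child.generate_state(2) >> 1)
        design = build_session(design_name, s_schedule, counts)
        trajs = simulate_session(design, lp, replace(noise, seed=s_noise))
        out.append((design, trajs))
    return out


def hidden_state_table(trajectories: Sequence[Trajectory]) -> pd.DataFrame:
    """Per-trial hidden-state audit table (states after each trial)."""
    return pd.DataFrame(
        {
            "trial_index": [t.spec.index for t in trajectories],
            "z_shared": [t.hidden_state.z_shared for t in trajectories],
            "z_reach": [t.hidden_state.z_reach for t in trajectories],
            "z_track": [t.hidden_state.z_track for t in trajectories],
        }
    )
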
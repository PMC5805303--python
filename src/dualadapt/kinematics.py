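"""Per-trial signal processing and kinematic outcome measures.

The processing chain for each trial is: low-pass filter the sampled planar
positions (first-order Butterworth, 2.5 Hz cutoff at 50 Hz sampling),
differentiate to a speed profile, locate movement onset and offset relative
to peak speed (10% of peak for reaches, 33% for tracking), then score the
trial — signed angular error of the cursor relative to the target at peak
speed for reaches, root-mean-square cursor-to-target distance for tracking,
plus pursuit latency / onset-distance / movement-time descriptors.

Angles are degrees, CCW-positive, measured from the home position and
wrapped to (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy import signal

from .paradigm import MovementType

if TYPE_CHECKING:  # pragma: no cover
    from .simulator import Trajectory

__all__ = [
    "FilterSpec",
    "TrialMeasures",
    "wrap_angle_deg",
    "lowpass_filter",
    "speed_profile",
    "movement_onset",
    "movement_offset",
    "angular_error_at_peak_velocity",
    "tracking_rmse",
    "pursuit_descriptors",
    "analyze_trial",
    "measures_table",
]

REACH_ONSET_FRACTION = 0.10
TRACK_ONSET_FRACTION = 0.33
OFFSET_FRACTION = 0.33


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth smoothing parameters.

    ``zero_phase`` applies the filter forward and backward (no group delay;
    the squared single-pass magnitude response); single-pass mode is kept as
    an option.
    """

    order: int = 1
    cutoff_hz: float = 2.5
    fs_hz: float = 50.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.cutoff_hz < self.fs_hz / 2:
            raise ValueError("cutoff must lie in (0, Nyquist)")
        if self.order < 1:
            raise ValueError("order must be >= 1")


def wrap_angle_deg(angle: np.ndarray | float) -> np.ndarray | float:
    """Wrap degrees into (-180, 180]."""
    wrapped = -np.mod(-np.asarray(angle, dtype=float) + 180.0, 360.0) + 180.0
    return float(wrapped) if np.isscalar(angle) else wrapped


def lowpass_filter(series: np.ndarray, spec: FilterSpec | None = None) -> np.ndarray:
    """Filter each coordinate of an (n, 2) position series independently.

    Unit DC gain: constants pass unchanged.
    """
    spec = spec or FilterSpec()
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
        squeeze = True
    else:
        squeeze = False
    if len(series) < 5:
        raise ValueError("need at least 5 samples to filter")
    b, a = signal.butter(spec.order, spec.cutoff_hz, fs=spec.fs_hz)
    if spec.zero_phase:
        out = signal.filtfilt(b, a, series, axis=0)
    else:
        # initialize at DC steady state for the first sample so constants
        # pass unchanged (unit DC gain, no startup transient)
        zi = signal.lfilter_zi(b, a)
        out = np.empty_like(series)
        for j in range(series.shape[1]):
            out[:, j], _ = signal.lfilter(b, a, series[:, j], zi=zi * series[0, j])
    return out[:, 0] if squeeze else out


def speed_profile(xy: np.ndarray, fs_hz: float) -> np.ndarray:
    """Per-sample tangential speed (cm/s) by finite differences.

    Central differences in the interior, one-sided at the ends.
    """
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 3:
        raise ValueError("need at least 3 samples for a speed profile")
    vel = np.gradient(xy, 1.0 / fs_hz, axis=0)
    return np.hypot(vel[:, 0], vel[:, 1])


def _peak_index(speed: np.ndarray) -> int:
    # Global maximum; earliest sample wins ties.
    return int(np.argmax(speed))


def movement_onset(speed: np.ndarray, fraction: float) -> int:
    """Index where the movement crosses ``fraction`` of peak speed, rising.

    Scans backward from the (earliest) global peak: the onset is one past the
    latest below-threshold sample before the peak.
    """
    speed = np.asarray(speed, dtype=float)
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    peak = _peak_index(speed)
    if speed[peak] <= 0:
        raise ValueError("no movement: peak speed is zero")
    threshold = fraction * speed[peak]
    idx = peak
    while idx > 0 and speed[idx - 1] >= threshold:
        idx -= 1
    return idx


def movement_offset(speed: np.ndarray, fraction: float = OFFSET_FRACTION) -> tuple[int, bool]:
    """Index where the movement falls below ``fraction`` of peak speed.

    Returns ``(index, clipped)``: the last sample at or above threshold after
    the peak. ``clipped`` is True when speed never drops below threshold and
    the final sample is returned.
    """
    speed = np.asarray(speed, dtype=float)
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    peak = _peak_index(speed)
    if speed[peak] <= 0:
        raise ValueError("no movement: peak speed is zero")
    threshold = fraction * speed[peak]
    for k in range(peak + 1, len(speed)):
        if speed[k] < threshold:
            return k - 1, False
    return len(speed) - 1, True


def angular_error_at_peak_velocity(
    cursor_xy: np.ndarray,
    target_pos: np.ndarray,
    home: np.ndarray | tuple[float, float] = (0.0, 0.0),
    peak_index: int | None = None,
    fs_hz: float = 50.0,
) -> float:
    """Signed cursor-minus-target direction difference at peak speed (deg).

    Both directions are measured from the home position; the result is
    CCW-positive and wrapped to (-180, 180]. ``peak_index`` may be supplied
    (e.g. from a filtered speed profile); otherwise it is located from the
    raw cursor series.
    """
    cursor_xy = np.asarray(cursor_xy, dtype=float)
    home = np.asarray(home, dtype=float)
    if peak_index is None:
        peak_index = _peak_index(speed_profile(cursor_xy, fs_hz))
    c = cursor_xy[peak_index] - home
    g = np.asarray(target_pos, dtype=float) - home
    if np.hypot(*c) < 1e-12:
        raise ValueError("cursor at home at peak velocity: direction undefined")
    return float(
        wrap_angle_deg(np.degrees(np.arctan2(c[1], c[0]) - np.arctan2(g[1], g[0])))
    )


def tracking_rmse(cursor_xy: np.ndarray, target_xy: np.ndarray) -> float:
    """Root-mean-square Euclidean cursor-to-target distance (cm)."""
    cursor_xy = np.asarray(cursor_xy, dtype=float)
    target_xy = np.asarray(target_xy, dtype=float)
    if cursor_xy.shape != target_xy.shape:
        raise ValueError("cursor and target series must have equal shapes")
    if len(cursor_xy) < 1:
        raise ValueError("need at least one sample")
    d2 = np.sum((cursor_xy - target_xy) ** 2, axis=1)
    return float(np.sqrt(np.mean(d2)))


def _target_halt_index(target_xy: np.ndarray) -> int:
    """First sample at which the target has reached its final position."""
    final = target_xy[-1]
    at_final = np.all(np.isclose(target_xy, final, atol=1e-9), axis=1)
    # last run of True at the tail
    idx = len(target_xy) - 1
    while idx > 0 and at_final[idx - 1]:
        idx -= 1
    return idx


def _target_motion_start_index(target_xy: np.ndarray) -> int:
    """Last sample before the target leaves its initial position."""
    moved = ~np.all(np.isclose(target_xy, target_xy[0], atol=1e-9), axis=1)
    if not moved.any():
        return 0
    return max(int(np.argmax(moved)) - 1, 0)


def pursuit_descriptors(
    t_ms: np.ndarray,
    cursor_xy: np.ndarray,
    target_xy: np.ndarray,
    fs_hz: float = 50.0,
    onset_fraction: float = TRACK_ONSET_FRACTION,
) -> tuple[float, float, float]:
    """(pursuit latency ms, cursor-to-target onset distance cm, movement time ms).

    Latency is the lag between target-motion start and cursor-movement onset
    (33% of peak speed); onset distance is the cursor-target separation at
    that sample; movement time runs from onset to offset (33% criterion).
    """
    t_ms = np.asarray(t_ms, dtype=float)
    speed = speed_profile(cursor_xy, fs_hz)
    onset = movement_onset(speed, onset_fraction)
    offset, _ = movement_offset(speed, OFFSET_FRACTION)
    start = _target_motion_start_index(np.asarray(target_xy, dtype=float))
    latency = float(t_ms[onset] - t_ms[start])
    onset_distance = float(np.hypot(*(cursor_xy[onset] - target_xy[onset])))
    movement_time = float(t_ms[offset] - t_ms[onset])
    return latency, onset_distance, movement_time


@dataclass
class TrialMeasures:
    """Kinematic outcomes for one trial."""

    trial_index: int
    phase: str
    movement_type: str
    target_angle_deg: float
    rotation_deg: float
    peak_speed_cm_s: float
    onset_index: int
    offset_index: int
    offset_clipped: bool
    angular_error_deg: float
    movement_time_ms: float
    rmse_cm: float | None = None
    pursuit_latency_ms: float | None = None
    onset_distance_cm: float | None = None


def analyze_trial(
    traj: "Trajectory",
    filter_spec: FilterSpec | None = None,
    home: tuple[float, float] = (0.0, 0.0),
) -> TrialMeasures:
    """Run the full filter -> onset/offset -> measures pipeline on one trial.

    Cursor-visible trials are scored on the cursor; no-cursor trials on the
    hand (open-loop reach error). Tracking RMSE is evaluated from
    target-motion onset through target halt.
    """
    spec = traj.spec
    series = traj.cursor_xy_cm if spec.cursor_visible else traj.hand_xy_cm
    fs = 1000.0 / float(traj.t_ms[1] - traj.t_ms[0])
    fspec = filter_spec or FilterSpec(fs_hz=fs)
    filt = lowpass_filter(series, fspec)
    speed = speed_profile(filt, fs)
    is_track = spec.movement_type is MovementType.TRACK
    onset = movement_onset(speed, TRACK_ONSET_FRACTION if is_track else REACH_ONSET_FRACTION)
    offset, clipped = movement_offset(speed, OFFSET_FRACTION)
    peak = _peak_index(speed)
    target_final = np.asarray(traj.target_xy_cm[-1], dtype=float)
    error = angular_error_at_peak_velocity(filt, target_final, home, peak_index=peak)
    measures = TrialMeasures(
        trial_index=spec.index,
        phase=spec.phase.value,
        movement_type=spec.movement_type.value,
        target_angle_deg=spec.target_angle_deg,
        rotation_deg=spec.rotation_deg,
        peak_speed_cm_s=float(speed[peak]),
        onset_index=onset,
        offset_index=offset,
        offset_clipped=clipped,
        angular_error_deg=error,
        movement_time_ms=float(traj.t_ms[offset] - traj.t_ms[onset]),
    )
    if is_track:
        halt = _target_halt_index(np.asarray(traj.target_xy_cm, dtype=float))
        start = _target_motion_start_index(np.asarray(traj.target_xy_cm, dtype=float))
        measures.rmse_cm = tracking_rmse(
            filt[start : halt + 1], traj.target_xy_cm[start : halt + 1]
        )
        latency, onset_dist, mt = pursuit_descriptors(
            traj.t_ms, filt, traj.target_xy_cm, fs
        )
        measures.pursuit_latency_ms = latency
        measures.onset_distance_cm = onset_dist
        measures.movement_time_ms = mt
    return measures


def measures_table(
    trajectories,
    filter_spec: FilterSpec | None = None,
    design: str | None = None,
    participant_id: int | None = None,
) -> pd.DataFrame:
    """Per-trial measures for a whole session as a flat table."""
    rows = []
    for traj in trajectories:
        m = analyze_trial(traj, filter_spec)
        row = vars(m).copy()
        if design is not None:
            row["design"] = design
        if participant_id is not None:
            row["participant_id"] = participant_id
        rows.append(row)
    return pd.DataFrame(rows)
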
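"""Tabular trajectory interchange, run configuration, and test fixtures.

Trajectories travel as flat RFC-4180 CSV, one row per 50 Hz sample, with
angles in degrees, positions in cm and times in ms. Cursor columns are empty
on no-cursor rows. The same format is written by the simulator and accepted
from users with their own recordings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .kinematics import FilterSpec
from .paradigm import (
    MovementType,
    Phase,
    SessionCounts,
    SessionDesign,
    TargetGeometry,
    TrialSpec,
    build_session,
)
from .simulator import LearnerParams, NoiseParams, Trajectory

__all__ = [
    "TRAJECTORY_COLUMNS",
    "SchemaError",
    "RunConfig",
    "write_trajectories",
    "read_trajectories",
    "trajectories_to_table",
    "table_to_trajectories",
    "load_config",
    "save_config",
    "config_hash",
    "make_fixtures",
]

TRAJECTORY_COLUMNS = [
    "session_id",
    "participant_id",
    "trial_index",
    "design",
    "phase",
    "movement_type",
    "target_angle_deg",
    "rotation_deg",
    "t_ms",
    "hand_x_cm",
    "hand_y_cm",
    "cursor_x_cm",
    "cursor_y_cm",
    "target_x_cm",
    "target_y_cm",
    "cursor_visible",
]

SAMPLE_STEP_MS = 20.0  # 50 Hz


class SchemaError(ValueError):
    """A trajectory table violated the declared schema."""


@dataclass
class RunConfig:
    """Everything a run depends on, carried by value for provenance."""

    design: str = "DUAL"
    participants: int = 16
    seed: int = 0
    learner: LearnerParams = field(default_factory=LearnerParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    filter: FilterSpec = field(default_factory=FilterSpec)
    counts: SessionCounts = field(default_factory=SessionCounts)
    block_size: int = 5
    aftereffect_baseline: str = "final"
    fit_bound_a: float = 5.0
    log_level: str = "INFO"


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of a configuration for result provenance."""
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = dict(raw)
    for key, cls in (
        ("learner", LearnerParams),
        ("noise", NoiseParams),
        ("filter", FilterSpec),
        ("counts", SessionCounts),
    ):
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = cls(**kwargs[key])
    return RunConfig(**kwargs)


def trajectories_to_table(
    trajectories: Sequence[Trajectory],
    design: str,
    session_id: str = "s0",
    participant_id: int = 0,
) -> pd.DataFrame:
    """Flatten simulated trajectories into the interchange table."""
    frames = []
    for traj in trajectories:
        spec = traj.spec
        n = len(traj.t_ms)
        cursor = (
            traj.cursor_xy_cm
            if traj.cursor_xy_cm is not None
            else np.full((n, 2), np.nan)
        )
        frames.append(
            pd.DataFrame(
                {
                    "session_id": session_id,
                    "participant_id": participant_id,
                    "trial_index": spec.index,
                    "design": design,
                    "phase": spec.phase.value,
                    "movement_type": spec.movement_type.value,
                    "target_angle_deg": spec.target_angle_deg,
                    "rotation_deg": spec.rotation_deg,
                    "t_ms": traj.t_ms,
                    "hand_x_cm": traj.hand_xy_cm[:, 0],
                    "hand_y_cm": traj.hand_xy_cm[:, 1],
                    "cursor_x_cm": cursor[:, 0],
                    "cursor_y_cm": cursor[:, 1],
                    "target_x_cm": traj.target_xy_cm[:, 0],
                    "target_y_cm": traj.target_xy_cm[:, 1],
                    "cursor_visible": spec.cursor_visible,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def validate_table(df: pd.DataFrame) -> None:
    """Raise :class:`SchemaError` with row-level detail on any violation."""
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    rem = np.mod(df["t_ms"].to_numpy(dtype=float), SAMPLE_STEP_MS)
    bad = np.flatnonzero(np.minimum(rem, SAMPLE_STEP_MS - rem) > 1e-6)
    if bad.size:
        raise SchemaError(
            f"t_ms must be multiples of {SAMPLE_STEP_MS} ms (50 Hz); first bad row {bad[0]}"
        )
    for (sid, pid, idx), g in df.groupby(["session_id", "participant_id", "trial_index"]):
        t = g["t_ms"].to_numpy(dtype=float)
        dt = np.diff(t)
        if (dt <= 0).any():
            row = g.index[1 + int(np.argmax(dt <= 0))]
            raise SchemaError(f"non-monotone time in trial {idx} at row {row}")
        if dt.size and not np.allclose(dt, SAMPLE_STEP_MS, atol=1e-6):
            row = g.index[1 + int(np.argmax(~np.isclose(dt, SAMPLE_STEP_MS, atol=1e-6)))]
            raise SchemaError(
                f"mixed sampling rate in trial {idx} at row {row}: expected 20 ms steps"
            )
        visible = g["cursor_visible"].astype(bool)
        has_cursor = g[["cursor_x_cm", "cursor_y_cm"]].notna().all(axis=1)
        mism = visible != has_cursor
        if mism.any():
            raise SchemaError(
                f"cursor columns must be empty exactly on no-cursor rows; "
                f"trial {idx}, row {g.index[int(np.argmax(mism.to_numpy()))]}"
            )


def write_trajectories(table: pd.DataFrame | Sequence[Trajectory], path, **kwargs) -> None:
    """Write the interchange CSV (lossless full-precision floats)."""
    if not isinstance(table, pd.DataFrame):
        table = trajectories_to_table(table, **kwargs)
    validate_table(table)
    table.to_csv(path, index=False)


def read_trajectories(path) -> pd.DataFrame:
    """Read and validate an interchange CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    validate_table(df)
    return df


def table_to_trajectories(df: pd.DataFrame) -> list[Trajectory]:
    """Rebuild per-trial :class:`Trajectory` objects from a table.

    TRACK target durations are recovered from the sampled target path (first
    sample at which the target holds its final position). Hidden states are
    not part of the interchange format and come back zeroed.
    """
    from .simulator import LearnerState

    out = []
    for (_, _, idx), g in df.groupby(["session_id", "participant_id", "trial_index"], sort=True):
        g = g.sort_values("t_ms")
        t = g["t_ms"].to_numpy(dtype=float)
        target = g[["target_x_cm", "target_y_cm"]].to_numpy(dtype=float)
        mt = MovementType(g["movement_type"].iloc[0])
        duration = None
        if mt is MovementType.TRACK:
            final = target[-1]
            at_final = np.all(np.isclose(target, final, atol=1e-9), axis=1)
            k = len(target) - 1
            while k > 0 and at_final[k - 1]:
                k -= 1
            duration = float(t[k])
        spec = TrialSpec(
            index=int(idx),
            movement_type=mt,
            phase=Phase(g["phase"].iloc[0]),
            target_angle_deg=float(g["target_angle_deg"].iloc[0]),
            rotation_deg=float(g["rotation_deg"].iloc[0]),
            target_duration_ms=duration,
            cursor_visible=bool(g["cursor_visible"].iloc[0]),
        )
        cursor = g[["cursor_x_cm", "cursor_y_cm"]].to_numpy(dtype=float)
        out.append(
            Trajectory(
                t_ms=t,
                hand_xy_cm=g[["hand_x_cm", "hand_y_cm"]].to_numpy(dtype=float),
                cursor_xy_cm=None if not spec.cursor_visible else cursor,
                target_xy_cm=target,
                spec=spec,
                hidden_state=LearnerState(),
            )
        )
    return out


def make_fixtures(seed: int) -> dict[str, SessionDesign]:
    """Miniature deterministic sessions (5-trial phases) for fast tests.

    All schedule invariants are preserved: permutation blocks, the tracking
    duration ramp start, phase ordering.
    """
    counts = SessionCounts(
        aligned_reach=5, no_cursor=5, aligned_track=5, mixed_per_type=5, training_per_type=10
    )
    return {
        name: build_session(name, seed, counts)
        for name in ("SINGLE_REACH", "SINGLE_TRACK", "DUAL")
    }
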
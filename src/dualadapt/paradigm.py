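"""Experimental designs for dual visuomotor-rotation adaptation sessions.

Three session designs are supported, mirroring a planar tablet paradigm in
which participants either reach to static targets or pursue a moving target
(manual tracking), with the on-screen cursor optionally rotated about the
home position:

``SINGLE_REACH``
    Reach-only training under a 30 deg clockwise (CW, -30 deg) rotation.
``SINGLE_TRACK``
    Tracking-only training under a 30 deg counter-clockwise (CCW, +30 deg)
    rotation, with reach baselines to measure transfer.
``DUAL``
    Interleaved reach (-30 deg) and tracking (+30 deg) training: opposing
    rotations cued only by movement type.

Coordinate conventions used throughout the package: home at the origin,
x rightward, y away from the body, angles in degrees CCW-positive from +x,
rotations applied about home, CW encoded as negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TARGET_ANGLES_DEG",
    "ROTATION_CW_DEG",
    "ROTATION_CCW_DEG",
    "MovementType",
    "Phase",
    "TargetGeometry",
    "TrialSpec",
    "SessionCounts",
    "SessionDesign",
    "build_session",
    "track_duration",
    "target_path",
    "pseudo_random_order",
    "feedback_color",
    "session_manifest",
]

#: The five radially spaced target directions (deg CCW from +x).
TARGET_ANGLES_DEG: tuple[float, ...] = (60.0, 75.0, 90.0, 105.0, 120.0)

ROTATION_CW_DEG = -30.0
ROTATION_CCW_DEG = +30.0

#: Target travel-time ramp during baseline tracking familiarization (ms).
TRACK_RAMP_START_MS = 1800.0
TRACK_RAMP_STEP_MS = 20.0
TRACK_STEADY_MS = 1500.0


class MovementType(str, Enum):
    REACH = "REACH"
    TRACK = "TRACK"
    NOCURSOR_REACH = "NOCURSOR_REACH"


class Phase(str, Enum):
    ALIGNED_REACH = "aligned_reach"
    ALIGNED_REACH_NC = "aligned_reach_nc"
    ALIGNED_TRACK = "aligned_track"
    ALIGNED_TRACK_NC = "aligned_track_nc"
    ALIGNED_MIXED = "aligned_mixed"
    ROTATED_TRAIN = "rotated_train"
    ROTATED_NC = "rotated_nc"


@dataclass(frozen=True)
class TargetGeometry:
    """Workspace geometry: home position, target ring and marker sizes (cm)."""

    home_cm: tuple[float, float] = (0.0, 0.0)
    target_angles_deg: tuple[float, ...] = TARGET_ANGLES_DEG
    target_radius_cm: float = 12.0
    target_diameter_cm: float = 1.5
    cursor_diameter_cm: float = 1.0
    home_diameter_cm: float = 1.6

    def __post_init__(self) -> None:
        if len(set(self.target_angles_deg)) != 5:
            raise ValueError("geometry requires exactly 5 distinct target angles")
        if self.target_radius_cm <= 0:
            raise ValueError("target radius must be positive")

    @property
    def overlap_threshold_cm(self) -> float:
        """Center-to-center distance at which cursor and target overlap."""
        return (self.target_diameter_cm + self.cursor_diameter_cm) / 2.0

    def target_position(self, angle_deg: float) -> np.ndarray:
        """Final target position for a given direction (cm)."""
        a = np.deg2rad(angle_deg)
        return np.asarray(self.home_cm, dtype=float) + self.target_radius_cm * np.array(
            [np.cos(a), np.sin(a)]
        )


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial.

    ``target_duration_ms`` is the target travel time and applies to TRACK
    trials only; REACH and no-cursor trials are self-paced and carry None.
    """

    index: int
    movement_type: MovementType
    phase: Phase
    target_angle_deg: float
    rotation_deg: float
    target_duration_ms: float | None = None
    cursor_visible: bool = True

    def __post_init__(self) -> None:
        if self.rotation_deg not in (ROTATION_CW_DEG, 0.0, ROTATION_CCW_DEG):
            raise ValueError(f"rotation must be -30, 0 or +30 deg, got {self.rotation_deg}")
        if self.cursor_visible == (self.movement_type is MovementType.NOCURSOR_REACH):
            raise ValueError("cursor_visible must be False exactly for no-cursor trials")
        if self.movement_type is MovementType.TRACK:
            if self.target_duration_ms is None or not (
                TRACK_STEADY_MS <= self.target_duration_ms <= TRACK_RAMP_START_MS
            ):
                raise ValueError("TRACK trials need target_duration_ms in [1500, 1800]")
        elif self.target_duration_ms is not None:
            raise ValueError("only TRACK trials carry a target duration")


@dataclass(frozen=True)
class SessionCounts:
    """Per-phase trial counts; the defaults are the full study design.

    Override with smaller multiples of 5 for scaled-down test sessions.
    """

    aligned_reach: int = 50
    no_cursor: int = 30
    aligned_track: int = 65
    mixed_per_type: int = 25
    training_per_type: int = 180

    def __post_init__(self) -> None:
        for name in ("aligned_reach", "no_cursor", "aligned_track", "mixed_per_type", "training_per_type"):
            n = getattr(self, name)
            if n <= 0 or n % 5:
                raise ValueError(f"{name} must be a positive multiple of 5, got {n}")


@dataclass
class SessionDesign:
    """An ordered trial schedule for one simulated participant."""

    name: str
    trials: list[TrialSpec]
    seed: int
    counts: SessionCounts = field(default_factory=SessionCounts)

    def phase_trials(self, phase: Phase) -> list[TrialSpec]:
        return [t for t in self.trials if t.phase is phase]


DESIGN_NAMES = ("SINGLE_REACH", "SINGLE_TRACK", "DUAL")


def track_duration(baseline_ordinal: int) -> float:
    """Target travel time (ms) for the n-th aligned tracking trial.

    The ramp starts at 1800 ms and shortens by 20 ms per trial until it
    reaches the 1500 ms steady state (from ordinal 16 onward). Rotated
    tracking trials always use 1500 ms.
    """
    if baseline_ordinal < 1:
        raise ValueError("baseline ordinal is 1-based")
    return max(TRACK_STEADY_MS, TRACK_RAMP_START_MS - TRACK_RAMP_STEP_MS * (baseline_ordinal - 1))


def pseudo_random_order(
    n: int, labels: Sequence[float], rng: np.random.Generator | int
) -> list[float]:
    """Pseudo-random target order: back-to-back permutations of ``labels``.

    Every label appears once before any repeats, so each consecutive block of
    ``len(labels)`` trials visits all targets exactly once.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("empty label set")
    if n % len(labels):
        raise ValueError(f"n={n} not divisible by the {len(labels)} labels")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out: list[float] = []
    for _ in range(n // len(labels)):
        out.extend(np.asarray(labels)[rng.permutation(len(labels))].tolist())
    return out


def feedback_color(distance_cm: float, geometry: TargetGeometry | None = None) -> str:
    """Classify cursor-to-target separation into the display color bands.

    Green while the cursor overlaps the target (center distance within the
    sum of the two radii), yellow out to 4 cm, orange out to 8 cm, red beyond.
    """
    if distance_cm < 0:
        raise ValueError("distance must be non-negative")
    geometry = geometry or TargetGeometry()
    if distance_cm <= geometry.overlap_threshold_cm:
        return "green"
    if distance_cm <= 4.0:
        return "yellow"
    if distance_cm <= 8.0:
        return "orange"
    return "red"


def target_path(
    spec: TrialSpec,
    geometry: TargetGeometry | None = None,
    fs_hz: float = 50.0,
    duration_ms: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled target positions for one trial.

    TRACK targets depart from home and travel radially outward at constant
    speed, covering the 12 cm in ``spec.target_duration_ms``. REACH (and
    no-cursor) targets are static at the final location; ``duration_ms``
    sets how long the static target is sampled (default 1000 ms).

    Returns ``(t_ms, xy_cm)`` with ``floor(duration * fs / 1000) + 1`` samples.
    """
    if fs_hz <= 0:
        raise ValueError("sampling rate must be positive")
    geometry = geometry or TargetGeometry()
    final = geometry.target_position(spec.target_angle_deg)
    home = np.asarray(geometry.home_cm, dtype=float)
    if spec.movement_type is MovementType.TRACK:
        dur = float(spec.target_duration_ms)
    else:
        dur = 1000.0 if duration_ms is None else float(duration_ms)
    n = int(np.floor(dur * fs_hz / 1000.0)) + 1
    t_ms = np.arange(n) * (1000.0 / fs_hz)
    if spec.movement_type is MovementType.TRACK:
        frac = np.clip(t_ms / dur, 0.0, 1.0)[:, None]
        xy = home + frac * (final - home)
    else:
        xy = np.tile(final, (n, 1))
    return t_ms, xy


# ---------------------------------------------------------------------------
# Session construction
# ---------------------------------------------------------------------------

def _interleave_types(rng: np.random.Generator, n_per_type: int, max_run: int = 2) -> list[MovementType]:
    """Pseudo-random REACH/TRACK order for dual training.

    Types are shuffled within paired 10-trial blocks (5 of each) so that each
    type completes a full target permutation before repeating, with no more
    than ``max_run`` consecutive trials of either type.
    """
    seq: list[MovementType] = []
    for _ in range(n_per_type // 5):
        block = [MovementType.REACH] * 5 + [MovementType.TRACK] * 5
        for _attempt in range(10_000):
            cand = [block[i] for i in rng.permutation(10)]
            tail = seq[-max_run:] + cand
            ok = True
            run = 1
            for a, b in zip(tail, tail[1:]):
                run = run + 1 if a is b else 1
                if run > max_run:
                    ok = False
                    break
            if ok:
                seq.extend(cand)
                break
        else:  # pragma: no cover - rejection sampling essentially always succeeds
            raise RuntimeError("failed to interleave dual-training trial types")
    return seq


class _Builder:
    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.trials: list[TrialSpec] = []
        self.aligned_track_ordinal = 0

    def _targets(self, n: int) -> list[float]:
        return pseudo_random_order(n, TARGET_ANGLES_DEG, self.rng)

    def add_reach(self, n: int, phase: Phase, rotation: float = 0.0) -> None:
        for ang in self._targets(n):
            self.trials.append(
                TrialSpec(len(self.trials), MovementType.REACH, phase, ang, rotation)
            )

    def add_nocursor(self, n: int, phase: Phase) -> None:
        for ang in self._targets(n):
            self.trials.append(
                TrialSpec(
                    len(self.trials), MovementType.NOCURSOR_REACH, phase, ang, 0.0,
                    cursor_visible=False,
                )
            )

    def add_track(self, n: int, phase: Phase, rotation: float = 0.0) -> None:
        for ang in self._targets(n):
            if rotation == 0.0:
                self.aligned_track_ordinal += 1
                dur = track_duration(self.aligned_track_ordinal)
            else:
                dur = TRACK_STEADY_MS
            self.trials.append(
                TrialSpec(len(self.trials), MovementType.TRACK, phase, ang, rotation, dur)
            )

    def add_mixed_aligned(self, n_per_type: int) -> None:
        # Strict alternation starting with REACH; each type runs through its
        # own target permutations.
        reach_targets = iter(self._targets(n_per_type))
        track_targets = iter(self._targets(n_per_type))
        for i in range(2 * n_per_type):
            if i % 2 == 0:
                self.trials.append(
                    TrialSpec(
                        len(self.trials), MovementType.REACH, Phase.ALIGNED_MIXED,
                        next(reach_targets), 0.0,
                    )
                )
            else:
                self.aligned_track_ordinal += 1
                self.trials.append(
                    TrialSpec(
                        len(self.trials), MovementType.TRACK, Phase.ALIGNED_MIXED,
                        next(track_targets), 0.0,
                        track_duration(self.aligned_track_ordinal),
                    )
                )

    def add_dual_training(self, n_per_type: int) -> None:
        order = _interleave_types(self.rng, n_per_type)
        reach_targets = iter(self._targets(n_per_type))
        track_targets = iter(self._targets(n_per_type))
        for mt in order:
            if mt is MovementType.REACH:
                self.trials.append(
                    TrialSpec(
                        len(self.trials), MovementType.REACH, Phase.ROTATED_TRAIN,
                        next(reach_targets), ROTATION_CW_DEG,
                    )
                )
            else:
                self.trials.append(
                    TrialSpec(
                        len(self.trials), MovementType.TRACK, Phase.ROTATED_TRAIN,
                        next(track_targets), ROTATION_CCW_DEG, TRACK_STEADY_MS,
                    )
                )


def build_session(
    name: str, seed: int, counts: SessionCounts | None = None
) -> SessionDesign:
    """Construct the full trial schedule for one of the three designs.

    The same (name, seed, counts) always yields an identical schedule.
    """
    if name not in DESIGN_NAMES:
        raise ValueError(f"unknown design {name!r}; expected one of {DESIGN_NAMES}")
    if seed < 0:
        raise ValueError("seed must be non-negative")
    counts = counts or SessionCounts()
    b = _Builder(np.random.default_rng(seed))

    b.add_reach(counts.aligned_reach, Phase.ALIGNED_REACH)
    b.add_nocursor(counts.no_cursor, Phase.ALIGNED_REACH_NC)
    if name == "SINGLE_REACH":
        b.add_reach(counts.training_per_type, Phase.ROTATED_TRAIN, ROTATION_CW_DEG)
    else:
        b.add_track(counts.aligned_track, Phase.ALIGNED_TRACK)
        b.add_nocursor(counts.no_cursor, Phase.ALIGNED_TRACK_NC)
        if name == "SINGLE_TRACK":
            b.add_track(counts.training_per_type, Phase.ROTATED_TRAIN, ROTATION_CCW_DEG)
        else:  # DUAL
            b.add_mixed_aligned(counts.mixed_per_type)
            b.add_dual_training(counts.training_per_type)
    b.add_nocursor(counts.no_cursor, Phase.ROTATED_NC)
    return SessionDesign(name=name, trials=b.trials, seed=seed, counts=counts)


def session_manifest(design: SessionDesign) -> pd.DataFrame:
    """Flat per-trial table of a session schedule."""
    rows = [
        {
            "index": t.index,
            "design": design.name,
            "phase": t.phase.value,
            "movement_type": t.movement_type.value,
            "target_angle_deg": t.target_angle_deg,
            "rotation_deg": t.rotation_deg,
            "target_duration_ms": t.target_duration_ms,
            "cursor_visible": t.cursor_visible,
        }
        for t in design.trials
    ]
    return pd.DataFrame(rows)
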
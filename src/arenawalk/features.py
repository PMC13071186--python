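"""Behavioural feature extraction from conditioned trajectories.

All kinematic quantities are reported in mm / s units via the arena's
px-to-mm factor. Angles use arena coordinates: the image y axis is
flipped so that counter-clockwise (a left turn, seen from above) is
positive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .geometry import ArenaGeometry
from .tracking import Trajectory, TrackingConfig

__all__ = [
    "FEATURE_COLUMNS",
    "FEATURE_UNITS",
    "Kinematics",
    "WallStats",
    "TurnStats",
    "kinematics",
    "zone_times",
    "wall_interactions",
    "body_angles",
    "turning",
    "extract_features",
    "TrajectoryRecord",
    "build_feature_table",
]

TWO_PI = 2.0 * math.pi

#: The default classifier input row: ten locomotion / space-use features.
FEATURE_COLUMNS = [
    "distance", "mean_speed", "max_speed", "mean_abs_acceleration",
    "stop_time", "inner_time", "outer_time", "wall_contact_time",
    "thigmo_left", "thigmo_right",
]

FEATURE_UNITS = {
    "distance": "mm", "mean_speed": "mm/s", "max_speed": "mm/s",
    "mean_abs_acceleration": "mm/s^2", "stop_time": "s",
    "inner_time": "s", "outer_time": "s", "wall_contact_time": "s",
    "thigmo_left": "count", "thigmo_right": "count",
    "left_turns": "count", "right_turns": "count",
    "cumulative_rotation": "rad",
}


@dataclass
class Kinematics:
    distance: float
    mean_speed: float
    max_speed: float
    mean_abs_acceleration: float
    stop_time: float


def kinematics(traj: Trajectory, config: TrackingConfig,
               part: str = "body_centroid") -> Kinematics:
    """Distance (mm), speeds (mm/s), |acceleration| (mm/s^2), stop time (s).

    Speeds are per-displacement; the stop-time count assigns frame 0 the
    first displacement's speed so that every frame contributes.
    """
    xy = traj.part_xy(part)
    if len(xy) < 2:
        raise InvalidParameterError("need at least 2 frames")
    disp_px = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    disp_mm = disp_px * traj.px_to_mm
    speeds = disp_mm * traj.fps                      # n-1 values
    distance = float(np.nansum(disp_mm))
    accel = np.diff(speeds) * traj.fps               # n-2 values
    frame_speed = np.concatenate([[speeds[0]], speeds])
    stop_frames = int(np.sum(frame_speed < config.stop_speed))
    return Kinematics(
        distance=distance,
        mean_speed=float(np.nanmean(speeds)),
        max_speed=float(np.nanmax(speeds)),
        mean_abs_acceleration=float(np.nanmean(np.abs(accel))) if len(accel) else 0.0,
        stop_time=stop_frames / traj.fps,
    )


def zone_times(traj: Trajectory, arena: ArenaGeometry,
               part: str = "body_centroid") -> tuple[float, float]:
    """Seconds spent in the inner disc (r <= 2/3 R, boundary counts as
    inner) and in the outer annulus; they sum to the analysed duration."""
    xy = traj.part_xy(part)
    r = arena.dist_to_centre(xy)
    outside = r > arena.radius + arena.wall_band_px
    if outside.any():
        warnings.warn(f"{int(outside.sum())} positions outside the arena; clipped")
        r = np.minimum(r, arena.radius)
    inner = r <= arena.inner_radius
    return float(inner.sum() / traj.fps), float((~inner).sum() / traj.fps)


@dataclass
class WallStats:
    contact_time: float
    n_events: int


def wall_interactions(part_xy: np.ndarray, arena: ArenaGeometry, fps: float,
                      min_dwell: int = 2) -> WallStats:
    """Wall contact of one body part.

    Contact holds on frames with distance-to-centre >= R - 1 mm (the
    tolerance band of the wall). ``contact_time`` sums all contact
    frames; an *event* is an entry into the band (non-contact -> contact
    transition, or starting in contact), debounced by requiring at least
    ``min_dwell`` consecutive contact frames.
    """
    r = arena.dist_to_centre(np.asarray(part_xy, dtype=float))
    contact = r >= arena.contact_radius
    contact_time = float(np.nansum(contact) / fps)
    n_events = 0
    i, n = 0, len(contact)
    while i < n:
        if contact[i] and (i == 0 or not contact[i - 1]):
            j = i
            while j < n and contact[j]:
                j += 1
            if j - i >= min_dwell:
                n_events += 1
            i = j
        else:
            i += 1
    return WallStats(contact_time=contact_time, n_events=n_events)


def body_angles(head_xy: np.ndarray, back_xy: np.ndarray):
    """Body-axis angle per frame, arena coordinates, in [-pi, pi].

    alpha = arctan2(-(y_head - y_back), x_head - x_back): the image y
    axis is flipped so counter-clockwise is positive. Frames with
    coincident head and back carry the previous angle forward and are
    flagged invalid.
    """
    head = np.asarray(head_xy, dtype=float)
    back = np.asarray(back_xy, dtype=float)
    if head.shape != back.shape:
        raise InvalidParameterError("head and back series must be aligned")
    dx = head[:, 0] - back[:, 0]
    dy = -(head[:, 1] - back[:, 1])
    valid = ~((dx == 0) & (dy == 0)) & ~np.isnan(dx)
    angles = np.arctan2(dy, dx)
    prev = 0.0
    for i in range(len(angles)):
        if valid[i]:
            prev = angles[i]
        else:
            angles[i] = prev
    return angles, valid


@dataclass
class TurnStats:
    left_turns: int
    right_turns: int
    cumulative_rotation: float


def turning(angles: np.ndarray) -> TurnStats:
    """Count full turns from wrapped frame-to-frame angle differences.

    Differences are wrapped to (-pi, pi]; positive is a left
    (counter-clockwise) increment, negative a right one. Each time the
    accumulated rotation in one direction passes a multiple of 2*pi the
    corresponding full-turn counter increments; ``cumulative_rotation``
    is the signed running total.
    """
    angles = np.asarray(angles, dtype=float)
    if len(angles) < 2:
        raise InvalidParameterError("need at least 2 angles")
    d = np.diff(angles)
    d = np.mod(d + math.pi, TWO_PI) - math.pi
    d[d == -math.pi] = math.pi
    pos = float(d[d > 0].sum())
    neg = float(-d[d < 0].sum())
    eps = 1e-9
    return TurnStats(
        left_turns=int(math.floor(pos / TWO_PI + eps)),
        right_turns=int(math.floor(neg / TWO_PI + eps)),
        cumulative_rotation=float(d.sum()),
    )


def extract_features(traj: Trajectory, arena: ArenaGeometry,
                     config: TrackingConfig, min_dwell: int = 2) -> dict:
    """The full behavioural summary of one individual.

    Thigmotaxis is counted per antenna when antenna channels are present
    (one event per entry of the tip into the 1-mm wall band);
    ``wall_contact_time`` is the time either antenna tip (or, without
    antennae, the head) stays in the band. Missing parts yield NaN and
    set ``incomplete``.
    """
    feats: dict[str, float] = {}
    kin = kinematics(traj, config)
    feats.update(distance=kin.distance, mean_speed=kin.mean_speed,
                 max_speed=kin.max_speed,
                 mean_abs_acceleration=kin.mean_abs_acceleration,
                 stop_time=kin.stop_time)
    inner, outer = zone_times(traj, arena)
    feats.update(inner_time=inner, outer_time=outer)
    parts = set(traj.parts)
    incomplete = False
    if {"antenna_l", "antenna_r"} <= parts:
        wl = wall_interactions(traj.part_xy("antenna_l"), arena, traj.fps, min_dwell)
        wr = wall_interactions(traj.part_xy("antenna_r"), arena, traj.fps, min_dwell)
        feats["thigmo_left"] = wl.n_events
        feats["thigmo_right"] = wr.n_events
        rl = arena.dist_to_centre(traj.part_xy("antenna_l"))
        rr = arena.dist_to_centre(traj.part_xy("antenna_r"))
        either = (rl >= arena.contact_radius) | (rr >= arena.contact_radius)
        feats["wall_contact_time"] = float(np.nansum(either) / traj.fps)
    elif "head" in parts:
        wh = wall_interactions(traj.part_xy("head"), arena, traj.fps, min_dwell)
        feats["thigmo_left"] = np.nan
        feats["thigmo_right"] = np.nan
        feats["wall_contact_time"] = wh.contact_time
        incomplete = True
    else:
        feats["thigmo_left"] = feats["thigmo_right"] = np.nan
        feats["wall_contact_time"] = np.nan
        incomplete = True
    if {"head", "back"} <= parts:
        angles, _ = body_angles(traj.part_xy("head"), traj.part_xy("back"))
        t = turning(angles)
        feats["left_turns"] = t.left_turns
        feats["right_turns"] = t.right_turns
        feats["cumulative_rotation"] = t.cumulative_rotation
    else:
        feats["left_turns"] = feats["right_turns"] = np.nan
        feats["cumulative_rotation"] = np.nan
        incomplete = True
    feats["incomplete"] = incomplete
    return feats


@dataclass
class TrajectoryRecord:
    trajectory: Trajectory
    arena: ArenaGeometry
    group: str = ""
    sex: str = ""
    uid: str = ""


def build_feature_table(records: Iterable[TrajectoryRecord],
                        config: TrackingConfig,
                        min_dwell: int = 2) -> pd.DataFrame:
    """One FeatureVector row per individual, with group/sex labels."""
    rows = []
    for rec in records:
        feats = extract_features(rec.trajectory, rec.arena, config, min_dwell)
        feats.update(group=rec.group, sex=rec.sex, uid=rec.uid)
        rows.append(feats)
    if not rows:
        raise InvalidParameterError("no records supplied")
    cols = (["uid", "group", "sex"] + FEATURE_COLUMNS
            + ["left_turns", "right_turns", "cumulative_rotation", "incomplete"])
    return pd.DataFrame(rows)[cols]


def write_feature_table(table: pd.DataFrame, csv_path, units_json_path=None) -> None:
    table.to_csv(csv_path, index=False)
    if units_json_path is not None:
        import json
        from pathlib import Path
        Path(units_json_path).write_text(json.dumps(FEATURE_UNITS, indent=2))
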
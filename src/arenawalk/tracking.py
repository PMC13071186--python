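"""Keypoint time series: frame-by-frame labelling and conditioning.

The classical labeller fills the head and back channels; antenna channels
come from an external keypoint table or from simulation ground truth.
Conditioning follows the usual pose-tracking chain: short rolling-mean
smoothing, a low-pass speed filter that treats implausible jumps as
tracking errors, and linear interpolation across short detection gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .autolabel import LabelParams, label_frame
from .errors import ArenaWalkError, InvalidParameterError, TrackingError

__all__ = [
    "TrackingConfig",
    "Trajectory",
    "track_video",
    "smooth",
    "apply_speed_filter",
    "extract_segment",
    "interpolate_gaps",
]


@dataclass(frozen=True)
class TrackingConfig:
    """Conditioning parameters.

    ``px_to_mm`` defaults to the full-resolution calibration of the
    reference rig (1 px = 0.055 mm); synthetic arenas carry their own
    factor. ``speed_cap`` is the low-pass velocity threshold (implausible
    displacements are tracking errors); ``stop_speed`` the stop-bout
    threshold, both mm/s.
    """

    fps: float = 60.0
    px_to_mm: float = 0.055
    smooth_window: int = 3
    speed_cap: float = 50.0
    stop_speed: float = 0.5
    max_gap: int = 5
    segment_s: float | None = 120.0  # central segment length, seconds

    def __post_init__(self):
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise InvalidParameterError("smooth_window must be odd and >= 1")
        if not self.speed_cap > self.stop_speed > 0:
            raise InvalidParameterError("need speed_cap > stop_speed > 0")
        if self.fps <= 0 or self.px_to_mm <= 0:
            raise InvalidParameterError("fps and px_to_mm must be > 0")


@dataclass
class Trajectory:
    """Tidy keypoint table: one row per (frame, part).

    Columns: ``frame, part, x, y, likelihood``; px image coordinates.
    """

    data: pd.DataFrame
    fps: float
    px_to_mm: float

    def __post_init__(self):
        if self.fps <= 0 or self.px_to_mm <= 0:
            raise InvalidParameterError("fps and px_to_mm must be > 0")
        lk = self.data["likelihood"].to_numpy()
        if ((lk < 0) | (lk > 1)).any():
            raise InvalidParameterError("likelihood must be in [0, 1]")
        for _, sub in self.data.groupby("part"):
            f = sub["frame"].to_numpy()
            if (np.diff(f) <= 0).any():
                raise InvalidParameterError("frame indices must be strictly increasing")

    @property
    def parts(self) -> list[str]:
        return sorted(self.data["part"].unique())

    @property
    def n_frames(self) -> int:
        return int(self.data["frame"].nunique())

    def part_xy(self, part: str) -> np.ndarray:
        sub = self.data[self.data["part"] == part].sort_values("frame")
        return sub[["x", "y"]].to_numpy(dtype=float)

    def part_likelihood(self, part: str) -> np.ndarray:
        sub = self.data[self.data["part"] == part].sort_values("frame")
        return sub["likelihood"].to_numpy(dtype=float)

    @classmethod
    def from_parts(cls, parts: Mapping[str, np.ndarray], fps: float,
                   px_to_mm: float,
                   likelihood: Mapping[str, np.ndarray] | None = None) -> "Trajectory":
        rows = []
        for name, xy in parts.items():
            xy = np.asarray(xy, dtype=float)
            lk = (likelihood or {}).get(name, np.ones(len(xy)))
            rows.append(pd.DataFrame({
                "frame": np.arange(len(xy)), "part": name,
                "x": xy[:, 0], "y": xy[:, 1], "likelihood": lk}))
        return cls(pd.concat(rows, ignore_index=True), fps=fps, px_to_mm=px_to_mm)

    def with_parts(self, parts: Mapping[str, np.ndarray]) -> "Trajectory":
        """Replace coordinates of the given parts, keeping frames/likelihoods."""
        df = self.data.copy()
        for name, xy in parts.items():
            sel = df["part"] == name
            idx = df.loc[sel].sort_values("frame").index
            df.loc[idx, "x"] = np.asarray(xy)[:, 0]
            df.loc[idx, "y"] = np.asarray(xy)[:, 1]
        return Trajectory(df, fps=self.fps, px_to_mm=self.px_to_mm)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "fps", self.fps)
        out.insert(1, "px_to_mm", self.px_to_mm)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        fps = float(df.pop("fps").iloc[0]) if "fps" in df else 60.0
        mm = float(df.pop("px_to_mm").iloc[0]) if "px_to_mm" in df else 0.055
        if "likelihood" not in df:
            df["likelihood"] = 1.0
        return cls(df[["frame", "part", "x", "y", "likelihood"]], fps=fps, px_to_mm=mm)


def interpolate_gaps(xy: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly fill interior NaN runs of length <= max_gap; longer runs
    and edge runs are left missing."""
    xy = np.array(xy, dtype=float)
    bad = np.isnan(xy[:, 0])
    if not bad.any():
        return xy
    n = len(xy)
    i = 0
    while i < n:
        if not bad[i]:
            i += 1
            continue
        j = i
        while j < n and bad[j]:
            j += 1
        run = j - i
        if 0 < i and j < n and run <= max_gap:
            for k in range(i, j):
                w = (k - (i - 1)) / (j - (i - 1))
                xy[k] = (1 - w) * xy[i - 1] + w * xy[j]
        i = j
    return xy


def track_video(frames: Iterable[np.ndarray], config: TrackingConfig,
                params: LabelParams = LabelParams()) -> Trajectory:
    """Run the classical labeller on every frame.

    Frames where labelling fails get likelihood 0 and are linearly
    interpolated when the gap is at most ``config.max_gap``; the body
    centroid is the head/back midpoint.
    """
    heads, backs, ok = [], [], []
    prev_head = None
    for frame in frames:
        motion = None
        try:
            if prev_head is not None:
                motion = None  # area rule is orientation-free; no tie context kept
            h, b = label_frame(frame, params, motion_dir=motion)
            heads.append(h.centroid)
            backs.append(b.centroid)
            ok.append(True)
            prev_head = h.centroid
        except ArenaWalkError:
            heads.append((np.nan, np.nan))
            backs.append((np.nan, np.nan))
            ok.append(False)
    if len(heads) < 2:
        raise InvalidParameterError("need at least 2 frames")
    ok = np.array(ok)
    if not ok.any():
        raise TrackingError("labelling failed on every frame")
    head = interpolate_gaps(np.asarray(heads, dtype=float), config.max_gap)
    back = interpolate_gaps(np.asarray(backs, dtype=float), config.max_gap)
    centroid = (head + back) / 2.0
    lk = ok.astype(float)
    return Trajectory.from_parts(
        {"head": head, "back": back, "body_centroid": centroid},
        fps=config.fps, px_to_mm=config.px_to_mm,
        likelihood={"head": lk, "back": lk, "body_centroid": lk})


def smooth(traj: Trajectory, window: int = 3) -> Trajectory:
    """Centred rolling-mean smoothing per part; endpoints use truncated
    windows, so series length is preserved."""
    if window < 1 or window % 2 == 0:
        raise InvalidParameterError("window must be odd and >= 1")
    if window == 1:
        return replace(traj, data=traj.data.copy())
    new_parts = {}
    for part in traj.parts:
        xy = pd.DataFrame(traj.part_xy(part))
        sm = xy.rolling(window, center=True, min_periods=1).mean()
        new_parts[part] = sm.to_numpy()
    return traj.with_parts(new_parts)


@dataclass
class SpeedFilterResult:
    trajectory: Trajectory
    n_flagged: int
    flagged_frames: dict[str, np.ndarray]


def apply_speed_filter(traj: Trajectory, speed_cap: float) -> SpeedFilterResult:
    """Low-pass velocity filter: displacements implying a speed above
    ``speed_cap`` (mm/s) are tracking errors.

    A single forward pass keeps the last accepted position; a frame whose
    displacement from it exceeds the cap (for the elapsed time) is
    flagged, removed, and later filled by linear interpolation between
    accepted neighbours. Returns the filtered trajectory and the number
    of flagged frames.
    """
    if not speed_cap > 0:
        raise InvalidParameterError("speed_cap must be > 0")
    new_parts = {}
    flagged: dict[str, np.ndarray] = {}
    total = 0
    mm_per_frame_cap = speed_cap / traj.fps / traj.px_to_mm  # px per frame
    for part in traj.parts:
        xy = traj.part_xy(part).copy()
        n = len(xy)
        bad = np.zeros(n, dtype=bool)
        last_good = None
        for i in range(n):
            if np.isnan(xy[i, 0]):
                continue
            if last_good is None:
                last_good = i
                continue
            dt_frames = i - last_good
            dist = float(np.hypot(*(xy[i] - xy[last_good])))
            if dist > mm_per_frame_cap * dt_frames:
                bad[i] = True
            else:
                last_good = i
        if bad.any():
            xy[bad] = np.nan
            xy = interpolate_gaps(xy, max_gap=n)  # no gap limit here
        new_parts[part] = xy
        flagged[part] = np.flatnonzero(bad)
        total += int(bad.sum())
    return SpeedFilterResult(traj.with_parts(new_parts), total, flagged)


def extract_segment(traj: Trajectory, duration_s: float,
                    start_s: float | None = None) -> Trajectory:
    """Cut out exactly ``duration_s * fps`` frames; centred by default.

    The central two minutes of a recording avoid acclimation transients
    at the start and handling effects at the end.
    """
    n_keep = int(round(duration_s * traj.fps))
    frames = np.sort(traj.data["frame"].unique())
    if n_keep > len(frames):
        raise InvalidParameterError("segment longer than the recording")
    if start_s is None:
        i0 = (len(frames) - n_keep) // 2
    else:
        i0 = int(round(start_s * traj.fps))
        if i0 + n_keep > len(frames):
            raise InvalidParameterError("segment extends past the recording")
    keep = set(frames[i0:i0 + n_keep].tolist())
    df = traj.data[traj.data["frame"].isin(keep)].copy()
    df["frame"] = df["frame"] - frames[i0]
    return Trajectory(df.reset_index(drop=True), fps=traj.fps, px_to_mm=traj.px_to_mm)
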
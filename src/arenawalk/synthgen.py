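"""Synthetic arena recordings with exact ground truth.

The generator emulates a single dark, two-lobed walking insect (small head
lobe, larger back lobe) in a light circular dish. Motion is a correlated
random walk: a two-state stop/go Markov chain gates movement, heading
persists with wrapped-normal turning increments, and near the wall the
walker steers tangentially with a configurable probability (tunable
thigmotaxis). Every frame carries exact ground truth — lobe centroids,
antenna tips, stop/go state and the analytic silhouette — so each
downstream stage (segmentation, tracking, feature extraction,
classification) can be tested against a known answer.

Treated presets model sublethal-exposure phenotypes: lower mean speed,
longer stop bouts, and weaker wall-following than untreated controls.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import InvalidParameterError
from .geometry import ArenaGeometry

__all__ = [
    "MotionPreset",
    "BodyShape",
    "GroundTruth",
    "CohortMember",
    "default_arena",
    "default_presets",
    "simulate_trajectory",
    "render_frame",
    "render_video",
    "silhouette_masks",
    "truth_detections",
    "make_cohort",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class MotionPreset:
    """Parameters of the correlated random walk.

    Parameters
    ----------
    mean_speed:
        Mean walking speed while in the "go" state, mm/s.
    speed_dispersion:
        Coefficient of variation of the per-frame step length (gamma
        distributed around the configured mean). 0 gives constant steps.
    turn_kappa:
        Heading-persistence concentration; turning increments are
        N(0, 1/sqrt(kappa)) radians per moving frame.
    stop_rate, go_rate:
        Per-frame transition probabilities go->stop and stop->go.
    wall_bias:
        Probability of steering tangentially (wall following) on a moving
        frame spent inside the wall-approach band.
    indiv_cv:
        Between-individual coefficient of variation applied to mean_speed
        when a cohort is generated; emulates biological heterogeneity.
    """

    label: str
    mean_speed: float
    turn_kappa: float
    stop_rate: float
    go_rate: float
    wall_bias: float
    speed_dispersion: float = 0.3
    indiv_cv: float = 0.3

    def __post_init__(self):
        for name in ("stop_rate", "go_rate", "wall_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1], got {v}")
        if self.mean_speed <= 0:
            raise InvalidParameterError("mean_speed must be > 0")
        if self.turn_kappa <= 0:
            raise InvalidParameterError("turn_kappa must be > 0")
        if self.speed_dispersion < 0 or self.indiv_cv < 0:
            raise InvalidParameterError("dispersions must be >= 0")


def default_presets() -> dict[str, MotionPreset]:
    """Control and two treated presets (mildly and strongly affected).

    Treated presets have strictly lower configured mean speed and wall
    bias than control, with the mildly treated preset intermediate: the
    strongly treated group is easy to tell from control and harder to
    tell from the mildly treated one.
    """
    return {
        "control": MotionPreset("control", mean_speed=6.0, turn_kappa=8.0,
                                stop_rate=0.010, go_rate=0.050, wall_bias=0.70),
        "lc10": MotionPreset("lc10", mean_speed=4.2, turn_kappa=6.0,
                             stop_rate=0.020, go_rate=0.040, wall_bias=0.50),
        "lc30": MotionPreset("lc30", mean_speed=2.5, turn_kappa=4.0,
                             stop_rate=0.030, go_rate=0.025, wall_bias=0.30),
    }


@dataclass(frozen=True)
class BodyShape:
    """Rigid two-lobe body template, px.

    The body axis points from back to head. Lobe centres sit at
    ``+head_offset`` / ``-back_offset`` from the body centroid along the
    axis; antenna tips at ``antenna_length`` from the head-lobe centre at
    +/- ``antenna_angle_deg`` from the axis, anterior of the head.
    """

    back_semi_axes: tuple[float, float] = (13.0, 8.4)
    head_semi_axes: tuple[float, float] = (7.0, 6.0)
    back_offset: float = 9.0
    head_offset: float = 10.7
    antenna_length: float = 20.0
    antenna_angle_deg: float = 25.0

    def __post_init__(self):
        ha = self.head_semi_axes
        ba = self.back_semi_axes
        if not (ha[0] * ha[1] < ba[0] * ba[1]):
            raise InvalidParameterError("head lobe must be smaller than back lobe")
        # Lobes must overlap so the silhouette is one connected region.
        if self.head_offset + self.back_offset >= ha[0] + ba[0]:
            raise InvalidParameterError("lobes must overlap along the body axis")

    @property
    def rear_extent(self) -> float:
        return self.back_offset + self.back_semi_axes[0]

    @property
    def antenna_reach(self) -> float:
        """Radial reach of an antenna tip beyond the body centroid."""
        return self.head_offset + self.antenna_length * math.cos(
            math.radians(self.antenna_angle_deg))

    @property
    def margin(self) -> float:
        """Clearance kept between body centroid and the dish wall."""
        return self.rear_extent + 1.0

    def scaled(self, factor: float) -> "BodyShape":
        return BodyShape(
            back_semi_axes=(self.back_semi_axes[0] * factor, self.back_semi_axes[1] * factor),
            head_semi_axes=(self.head_semi_axes[0] * factor, self.head_semi_axes[1] * factor),
            back_offset=self.back_offset * factor,
            head_offset=self.head_offset * factor,
            antenna_length=self.antenna_length * factor,
            antenna_angle_deg=self.antenna_angle_deg,
        )


def default_arena(frame_shape: tuple[int, int] = (540, 960),
                  radius: float = 250.0, px_to_mm: float = 0.11) -> ArenaGeometry:
    """Dish centred in the frame; defaults give a 27.5 mm-radius dish."""
    h, w = frame_shape
    return ArenaGeometry(centre=(w / 2.0, h / 2.0), radius=radius, px_to_mm=px_to_mm)


@dataclass
class GroundTruth:
    """Exact per-frame state of one simulated recording.

    Positions are px in image coordinates (y down). ``heading`` is the
    body-axis angle in image coordinates; ``moving`` the go-state flag.
    """

    centroid: np.ndarray   # (n, 2)
    head: np.ndarray       # (n, 2) head-lobe centre
    back: np.ndarray       # (n, 2) back-lobe centre
    antenna_l: np.ndarray  # (n, 2) insect-left antenna tip
    antenna_r: np.ndarray  # (n, 2)
    heading: np.ndarray    # (n,)
    moving: np.ndarray     # (n,) bool
    arena: ArenaGeometry
    fps: float
    shape: BodyShape
    label: str = ""

    @property
    def n_frames(self) -> int:
        return len(self.centroid)

    def mean_moving_speed(self) -> float:
        """Empirical mean speed over go-state frames, mm/s."""
        disp = np.linalg.norm(np.diff(self.centroid, axis=0), axis=1)
        mov = self.moving[1:]
        if not mov.any():
            return 0.0
        return float(disp[mov].mean() * self.fps * self.arena.px_to_mm)

    def part_positions(self) -> dict[str, np.ndarray]:
        return {
            "head": self.head,
            "back": self.back,
            "body_centroid": self.centroid,
            "antenna_l": self.antenna_l,
            "antenna_r": self.antenna_r,
        }

    def to_csv(self, path) -> None:
        """Tidy long-format ground truth: frame, part, x, y."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["frame", "part", "x", "y"])
            for part, arr in self.part_positions().items():
                for t in range(self.n_frames):
                    w.writerow([t, part, f"{arr[t, 0]:.4f}", f"{arr[t, 1]:.4f}"])

    def write_arena_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.arena.to_dict(), indent=2))


def _wrap_angle(a: float) -> float:
    return (a + math.pi) % TWO_PI - math.pi


def simulate_trajectory(preset: MotionPreset, n_frames: int, fps: float,
                        arena: ArenaGeometry | None = None, seed: int = 0,
                        shape: BodyShape | None = None,
                        start: tuple[float, float] | None = None) -> GroundTruth:
    """Simulate one confined correlated random walk.

    The walker starts in the go state. Each frame the stop/go chain is
    updated first; on moving frames the heading receives a wrapped-normal
    increment, step length is gamma-distributed around
    ``mean_speed / fps``, and wall interaction is: with probability
    ``wall_bias`` when inside the approach band, steer along the wall
    (tangentially, tilted slightly outward so followers ride the wall
    with their antennae in the contact band), otherwise reflect off the
    wall. Antenna tips are clamped at the wall (flexion on contact).
    Identical ``(preset, seed)`` give identical output.
    """
    if n_frames < 2:
        raise InvalidParameterError("n_frames must be >= 2")
    if fps <= 0:
        raise InvalidParameterError("fps must be > 0")
    shape = shape or BodyShape()
    arena = arena or default_arena()
    body_length = shape.rear_extent + shape.head_offset + shape.head_semi_axes[0]
    if arena.radius <= body_length:
        raise InvalidParameterError("arena radius must exceed body length")

    rng = np.random.default_rng(seed)
    limit = arena.radius - shape.margin          # max centroid radius
    steer_radius = max(limit - 15.0, 0.5 * limit)  # wall-approach band
    step_mean = preset.mean_speed / (fps * arena.px_to_mm)
    turn_sd = 1.0 / math.sqrt(preset.turn_kappa)
    cv2 = preset.speed_dispersion ** 2

    wall_tilt = math.radians(20.0)  # outward tilt of wall-following heading

    cx, cy = arena.centre
    if start is None:
        r0 = 0.85 * limit * math.sqrt(rng.random())
        a0 = rng.uniform(0.0, TWO_PI)
        pos = np.array([cx + r0 * math.cos(a0), cy + r0 * math.sin(a0)])
    else:
        pos = np.asarray(start, dtype=float)
        if np.hypot(pos[0] - cx, pos[1] - cy) > limit:
            raise InvalidParameterError("start position too close to the wall")
    heading = rng.uniform(0.0, TWO_PI)
    moving = True

    centroid = np.empty((n_frames, 2))
    headings = np.empty(n_frames)
    states = np.empty(n_frames, dtype=bool)
    centroid[0] = pos
    headings[0] = heading
    states[0] = moving

    for t in range(1, n_frames):
        if moving:
            moving = rng.random() >= preset.stop_rate
        else:
            moving = rng.random() < preset.go_rate
        if moving:
            heading = _wrap_angle(heading + rng.normal(0.0, turn_sd))
            step = step_mean if cv2 == 0 else step_mean * rng.gamma(1.0 / cv2, cv2)
            d = math.hypot(pos[0] - cx, pos[1] - cy)
            if d >= steer_radius and rng.random() < preset.wall_bias:
                phi = math.atan2(pos[1] - cy, pos[0] - cx)
                cand1, cand2 = phi + math.pi / 2.0, phi - math.pi / 2.0
                tangent = cand1 if abs(_wrap_angle(heading - cand1)) <= abs(
                    _wrap_angle(heading - cand2)) else cand2
                # tilt from the tangent toward the outward radial
                sign = 1.0 if _wrap_angle(tangent - phi) > 0 else -1.0
                heading = _wrap_angle(tangent - sign * wall_tilt)
            prop = pos + step * np.array([math.cos(heading), math.sin(heading)])
            dp = math.hypot(prop[0] - cx, prop[1] - cy)
            if dp > limit:
                # reflect the heading about the local tangent
                nx, ny = (prop[0] - cx) / dp, (prop[1] - cy) / dp
                vx, vy = math.cos(heading), math.sin(heading)
                dot = vx * nx + vy * ny
                vx, vy = vx - 2.0 * dot * nx, vy - 2.0 * dot * ny
                heading = math.atan2(vy, vx)
                prop = pos + step * np.array([vx, vy])
                dp = math.hypot(prop[0] - cx, prop[1] - cy)
                if dp > limit:  # grazing corner case: clamp radially
                    prop = np.array([cx, cy]) + (limit / dp) * (prop - np.array([cx, cy]))
            pos = prop
        centroid[t] = pos
        headings[t] = heading
        states[t] = moving

    u = np.stack([np.cos(headings), np.sin(headings)], axis=1)
    head = centroid + shape.head_offset * u
    back = centroid - shape.back_offset * u
    da = math.radians(shape.antenna_angle_deg)
    # In image coordinates (y down) the insect's left is heading - da.
    ul = np.stack([np.cos(headings - da), np.sin(headings - da)], axis=1)
    ur = np.stack([np.cos(headings + da), np.sin(headings + da)], axis=1)
    antenna_l = head + shape.antenna_length * ul
    antenna_r = head + shape.antenna_length * ur
    # antennae flex on wall contact: clamp tips just inside the dish
    for tips in (antenna_l, antenna_r):
        rel = tips - np.array([cx, cy])
        r = np.linalg.norm(rel, axis=1)
        over = r > arena.radius - 0.5
        if over.any():
            tips[over] = (np.array([cx, cy])
                          + rel[over] * ((arena.radius - 0.5) / r[over])[:, None])
    return GroundTruth(centroid=centroid, head=head, back=back,
                       antenna_l=antenna_l, antenna_r=antenna_r,
                       heading=headings, moving=states, arena=arena,
                       fps=fps, shape=shape, label=preset.label)


def _ellipse_mask_window(shape_hw, centre, semi_axes, angle):
    """Boolean raster of a rotated ellipse, evaluated on a local window."""
    h, w = shape_hw
    a, b = semi_axes
    pad = max(a, b) + 2.0
    x0 = max(int(math.floor(centre[0] - pad)), 0)
    x1 = min(int(math.ceil(centre[0] + pad)) + 1, w)
    y0 = max(int(math.floor(centre[1] - pad)), 0)
    y1 = min(int(math.ceil(centre[1] + pad)) + 1, h)
    mask = np.zeros((h, w), dtype=bool)
    if x0 >= x1 or y0 >= y1:
        return mask
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx = xs - centre[0]
    dy = ys - centre[1]
    c, s = math.cos(angle), math.sin(angle)
    u = (dx * c + dy * s) / a
    v = (-dx * s + dy * c) / b
    mask[y0:y1, x0:x1] = u * u + v * v <= 1.0
    return mask


def silhouette_masks(truth: GroundTruth, index: int,
                     frame_shape: tuple[int, int] = (540, 960)):
    """(head_lobe, back_lobe) boolean rasters for one frame."""
    ang = float(truth.heading[index])
    head_m = _ellipse_mask_window(frame_shape, truth.head[index],
                                  truth.shape.head_semi_axes, ang)
    back_m = _ellipse_mask_window(frame_shape, truth.back[index],
                                  truth.shape.back_semi_axes, ang)
    return head_m, back_m


def truth_detections(truth: GroundTruth, index: int,
                     frame_shape: tuple[int, int] = (540, 960)):
    """Ground-truth head/back boxes and centroids from the lobe rasters.

    Returns ``(head, back)`` detections in the same form the automatic
    labeller produces, for scoring predictions against exact truth.
    """
    from .autolabel import PartDetection

    head_m, back_m = silhouette_masks(truth, index, frame_shape)
    dets = []
    for part, m in (("head", head_m), ("back", back_m)):
        ys, xs = np.nonzero(m)
        dets.append(PartDetection(
            part,
            (float(xs.min()), float(ys.min()),
             float(xs.max() + 1), float(ys.max() + 1)),
            (float(xs.mean()), float(ys.mean())), float(len(xs))))
    return dets[0], dets[1]


def render_frame(truth: GroundTruth | None, index: int = 0, *,
                 noise_sd: float = 5.0, frame_shape: tuple[int, int] = (540, 960),
                 bg_grey: int = 120, body_grey: int = 15,
                 draw_ring: bool = False, ring_grey: int = 90,
                 seed: int | None = None):
    """Render one frame; returns ``(image uint8, silhouette mask bool)``.

    The body is drawn as two overlapping dark ellipses on a light
    background, with optional dish-rim ring and additive Gaussian noise.
    With ``truth=None`` an empty background is rendered.
    """
    h, w = frame_shape
    img = np.full((h, w), float(bg_grey))
    if truth is not None and draw_ring:
        ys, xs = np.mgrid[0:h, 0:w]
        r = np.hypot(xs - truth.arena.centre[0], ys - truth.arena.centre[1])
        img[np.abs(r - truth.arena.radius) <= 1.5] = float(ring_grey)
    if truth is None:
        mask = np.zeros((h, w), dtype=bool)
    else:
        head_m, back_m = silhouette_masks(truth, index, frame_shape)
        mask = head_m | back_m
        img[mask] = float(body_grey)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), mask


def render_video(truth: GroundTruth, *, noise_sd: float = 5.0,
                 frame_shape: tuple[int, int] = (540, 960),
                 seed: int = 0, **kwargs) -> Iterator[np.ndarray]:
    """Lazily render every frame of a recording (images only)."""
    for i in range(truth.n_frames):
        img, _ = render_frame(truth, i, noise_sd=noise_sd,
                              frame_shape=frame_shape, seed=seed + i, **kwargs)
        yield img


@dataclass
class CohortMember:
    uid: str
    group: str
    sex: str
    truth: GroundTruth

    def frames(self, noise_sd: float = 5.0,
               frame_shape: tuple[int, int] = (540, 960),
               seed: int = 0) -> Iterator[np.ndarray]:
        return render_video(self.truth, noise_sd=noise_sd,
                            frame_shape=frame_shape, seed=seed)


def make_cohort(presets: Mapping[str, MotionPreset] | None = None,
                sexes: Sequence[str] = ("male", "female"),
                n_per_cell: int = 32, n_frames: int = 1800, fps: float = 60.0,
                arena: ArenaGeometry | None = None, seed: int = 0,
                shape: BodyShape | None = None) -> list[CohortMember]:
    """Simulate one recording per individual of a groups x sexes design.

    Per-individual seeds are spawned from the master seed, and each
    individual's mean speed is jittered log-normally (cv ``indiv_cv``)
    around its preset to emulate between-animal variability. The default
    design (3 groups x 2 sexes x 32) yields 192 recordings.
    """
    presets = dict(presets) if presets is not None else default_presets()
    if not presets or not sexes or n_per_cell < 1:
        raise InvalidParameterError("design must have >= 1 group, sex and individual")
    arena = arena or default_arena()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(presets) * len(sexes) * n_per_cell)
    members: list[CohortMember] = []
    i = 0
    for gname, preset in presets.items():
        for sex in sexes:
            for k in range(n_per_cell):
                child_seed = int(children[i].generate_state(1)[0] % (2 ** 31))
                i += 1
                rng = np.random.default_rng(child_seed + 1)
                if preset.indiv_cv > 0:
                    sigma = math.sqrt(math.log(1.0 + preset.indiv_cv ** 2))
                    factor = float(rng.lognormal(-0.5 * sigma * sigma, sigma))
                else:
                    factor = 1.0
                indiv = replace(preset, mean_speed=preset.mean_speed * factor)
                truth = simulate_trajectory(indiv, n_frames, fps, arena,
                                            seed=child_seed, shape=shape)
                members.append(CohortMember(uid=f"{gname}_{sex}_{k:03d}",
                                            group=gname, sex=sex, truth=truth))
    return members
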
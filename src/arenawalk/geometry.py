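"""Circular-arena geometry.

Pixel coordinates follow the image convention: origin at the top-left,
x to the right, y downwards, 0-based. Distances in px unless noted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CollinearPointsError, InvalidParameterError

__all__ = ["ArenaGeometry", "fit_circle"]


@dataclass(frozen=True)
class ArenaGeometry:
    """A circular dish with a thigmotaxis wall band and an inner zone.

    The inner zone is the disc of radius ``inner_fraction * radius``; the
    wall-contact band is the annulus within ``wall_band_mm`` of the wall.
    """

    centre: tuple[float, float]
    radius: float
    px_to_mm: float = 0.11
    wall_band_mm: float = 1.0
    inner_fraction: float = 2.0 / 3.0

    def __post_init__(self):
        if self.radius <= 0:
            raise InvalidParameterError("arena radius must be > 0")
        if self.px_to_mm <= 0:
            raise InvalidParameterError("px_to_mm must be > 0")
        if not 0 < self.inner_fraction < 1:
            raise InvalidParameterError("inner_fraction must be in (0, 1)")

    @property
    def inner_radius(self) -> float:
        return self.inner_fraction * self.radius

    @property
    def wall_band_px(self) -> float:
        return self.wall_band_mm / self.px_to_mm

    @property
    def contact_radius(self) -> float:
        """Radial distance beyond which a point counts as wall contact."""
        return self.radius - self.wall_band_px

    def dist_to_centre(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        return np.hypot(xy[..., 0] - self.centre[0], xy[..., 1] - self.centre[1])

    def to_dict(self) -> dict:
        return {
            "centre": [float(self.centre[0]), float(self.centre[1])],
            "radius": float(self.radius),
            "px_to_mm": float(self.px_to_mm),
            "wall_band_mm": float(self.wall_band_mm),
            "inner_fraction": float(self.inner_fraction),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaGeometry":
        return cls(
            centre=(float(d["centre"][0]), float(d["centre"][1])),
            radius=float(d["radius"]),
            px_to_mm=float(d.get("px_to_mm", 0.11)),
            wall_band_mm=float(d.get("wall_band_mm", 1.0)),
            inner_fraction=float(d.get("inner_fraction", 2.0 / 3.0)),
        )


def fit_circle(p1, p2, p3, *, px_to_mm: float = 0.11, wall_band_mm: float = 1.0,
               inner_fraction: float = 2.0 / 3.0, tol: float = 1e-9) -> ArenaGeometry:
    """Circumscribed circle through three non-collinear points.

    The arena wall is digitised by clicking three points on the dish rim;
    the circumcentre/circumradius recover centre and radius exactly.

    Raises
    ------
    CollinearPointsError
        If the points are collinear within ``tol`` (relative to their span).
    """
    pts = np.asarray([p1, p2, p3], dtype=float)
    if len({tuple(p) for p in pts}) < 3:
        raise InvalidParameterError("points must be pairwise distinct")
    a, b, c = pts
    # 2x cross product of (b-a) and (c-a); zero iff collinear
    cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
    span = max(np.linalg.norm(b - a), np.linalg.norm(c - a), np.linalg.norm(c - b))
    if abs(cross) <= tol * span * span:
        raise CollinearPointsError("the three rim points are collinear")
    # Solve the two perpendicular-bisector equations
    A = 2.0 * np.array([[b[0] - a[0], b[1] - a[1]], [c[0] - a[0], c[1] - a[1]]])
    rhs = np.array([
        b[0] ** 2 - a[0] ** 2 + b[1] ** 2 - a[1] ** 2,
        c[0] ** 2 - a[0] ** 2 + c[1] ** 2 - a[1] ** 2,
    ])
    cx, cy = np.linalg.solve(A, rhs)
    radius = float(np.hypot(a[0] - cx, a[1] - cy))
    return ArenaGeometry(centre=(float(cx), float(cy)), radius=radius,
                         px_to_mm=px_to_mm, wall_band_mm=wall_band_mm,
                         inner_fraction=inner_fraction)
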
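"""Three-armed maze geometry and point-to-region classification.

The arena is a radially symmetric three-armed maze: an equilateral central
triangle (side 10 cm) with a rectangular arm (36.5 x 10 cm) attached to each
side. Entering an arm means leaving the central triangle across one of its
sides; the triangle itself is a decision zone that buffers arm membership.

Coordinate convention: the centroid of the central triangle is the origin,
arm 1's long axis points along +y, and arms are numbered counter-clockwise
(arm 2 at 210 degrees, arm 3 at 330 degrees). All geometry is in cm.

Region codes: 0 = center triangle, 1..3 = arms. Points on a region border are
assigned to the arm (a boundary touch counts as arm entry). Points slightly
outside the arena (tracking noise) are snapped to the nearest region within a
configurable tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import shapely
from shapely.geometry import Polygon

CENTER = 0
OUTSIDE = -1
MISSING = -2

ARM_CODES = (1, 2, 3)

REGION_LABELS = {CENTER: "center", 1: "arm_1", 2: "arm_2", 3: "arm_3"}


class OutOfArenaError(ValueError):
    """A tracked position lies farther outside the maze than the snap tolerance."""


@dataclass(frozen=True)
class MazeGeometry:
    """Physical layout of the three-armed maze plus camera calibration.

    Parameters
    ----------
    px_per_cm
        Camera calibration (pixels per cm); must be supplied explicitly, it is
        not recoverable from the maze dimensions.
    arm_length, arm_width, center_side
        Arm and central-triangle dimensions in cm.
    fps
        Video frame rate (frames per second).
    start_arm
        Arm containing the start compartment; fish that have not yet visited
        any arm are credited to it.
    snap_tolerance_cm
        Positions up to this far outside every region are snapped to the
        nearest region; beyond it classification raises ``OutOfArenaError``.
    """

    px_per_cm: float
    arm_length: float = 36.5
    arm_width: float = 10.0
    center_side: float = 10.0
    fps: float = 25.0
    start_arm: int = 1
    snap_tolerance_cm: float = 0.5

    def __post_init__(self) -> None:
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be > 0")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if min(self.arm_length, self.arm_width, self.center_side) <= 0:
            raise ValueError("maze dimensions must be > 0")
        if self.start_arm not in ARM_CODES:
            raise ValueError(f"start_arm must be one of {ARM_CODES}")
        if self.snap_tolerance_cm < 0:
            raise ValueError("snap_tolerance_cm must be >= 0")

    # -- derived geometry ----------------------------------------------------

    @property
    def apothem(self) -> float:
        """Centroid-to-side distance of the central triangle (cm)."""
        return self.center_side / (2.0 * np.sqrt(3.0))

    @cached_property
    def arm_axes(self) -> np.ndarray:
        """(3, 2) unit vectors along each arm's long axis, 120 deg apart."""
        angles = np.deg2rad(90.0 + 120.0 * np.arange(3))
        return np.column_stack([np.cos(angles), np.sin(angles)])

    @cached_property
    def arm_perps(self) -> np.ndarray:
        """(3, 2) unit vectors perpendicular to each arm axis."""
        ax = self.arm_axes
        return np.column_stack([-ax[:, 1], ax[:, 0]])

    def edge_midpoint(self, arm: int) -> np.ndarray:
        """Midpoint of the triangle side shared with ``arm`` (the arm mouth)."""
        return self.apothem * self.arm_axes[arm - 1]

    @cached_property
    def center_polygon(self) -> Polygon:
        circumradius = self.center_side / np.sqrt(3.0)
        angles = np.deg2rad([30.0, 150.0, 270.0])
        verts = circumradius * np.column_stack([np.cos(angles), np.sin(angles)])
        return Polygon(verts)

    @cached_property
    def arm_polygons(self) -> tuple[Polygon, Polygon, Polygon]:
        polys = []
        a, L, w = self.apothem, self.arm_length, self.arm_width
        for k in range(3):
            axis, perp = self.arm_axes[k], self.arm_perps[k]
            corners = [
                a * axis - 0.5 * w * perp,
                a * axis + 0.5 * w * perp,
                (a + L) * axis + 0.5 * w * perp,
                (a + L) * axis - 0.5 * w * perp,
            ]
            polys.append(Polygon(corners))
        return tuple(polys)

    @cached_property
    def region_polygons(self) -> dict[int, Polygon]:
        out: dict[int, Polygon] = {CENTER: self.center_polygon}
        for k, poly in zip(ARM_CODES, self.arm_polygons):
            out[k] = poly
        return out

    # -- serialization -------------------------------------------------------

    @classmethod
    def from_dict(cls, cfg: dict) -> "MazeGeometry":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown geometry fields: {sorted(unknown)}")
        if "px_per_cm" not in cfg:
            raise ValueError("geometry config must state px_per_cm explicitly")
        return cls(**cfg)

    def to_dict(self) -> dict:
        return {
            "px_per_cm": self.px_per_cm,
            "arm_length": self.arm_length,
            "arm_width": self.arm_width,
            "center_side": self.center_side,
            "fps": self.fps,
            "start_arm": self.start_arm,
            "snap_tolerance_cm": self.snap_tolerance_cm,
        }


def points_to_regions(
    xy: np.ndarray,
    geometry: MazeGeometry,
    *,
    on_outside: str = "raise",
) -> np.ndarray:
    """Classify points (cm) into maze regions.

    Parameters
    ----------
    xy
        (n, 2) array of positions in cm (maze-centred coordinates).
    on_outside
        ``"raise"``: points beyond the snap tolerance raise
        :class:`OutOfArenaError`. ``"code"``: such points get code ``OUTSIDE``
        (-1). Rows with NaN coordinates always get ``MISSING`` (-2).

    Returns
    -------
    np.ndarray of int8 region codes (0 = center, 1..3 = arms).

    Notes
    -----
    Border points belong to the arm, so touching the triangle side counts as
    arm entry. Points outside every region but within ``snap_tolerance_cm`` of
    one are snapped to the nearest region (nearest-distance ties prefer arms).
    """
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("xy must have shape (n, 2)")
    n = xy.shape[0]
    codes = np.full(n, OUTSIDE, dtype=np.int8)
    missing = ~np.isfinite(xy).all(axis=1)
    safe_xy = np.where(missing[:, None], 0.0, xy)

    a, L, half_w = geometry.apothem, geometry.arm_length, geometry.arm_width / 2.0
    u = safe_xy @ geometry.arm_axes.T  # (n, 3) axial coordinates
    v = safe_xy @ geometry.arm_perps.T  # (n, 3) lateral coordinates

    in_arm = (u >= a) & (u <= a + L) & (np.abs(v) <= half_w)
    # Arms are checked first: triangle-side points shared with an arm go to it.
    arm_idx = in_arm.argmax(axis=1)
    any_arm = in_arm.any(axis=1)
    codes[any_arm] = (arm_idx[any_arm] + 1).astype(np.int8)

    in_center = (u <= a).all(axis=1) & ~any_arm
    codes[in_center] = CENTER

    unresolved = ~any_arm & ~in_center & ~missing
    if unresolved.any():
        pts = shapely.points(safe_xy[unresolved])
        dists = np.column_stack(
            [shapely.distance(pts, geometry.region_polygons[k]) for k in (1, 2, 3, CENTER)]
        )
        nearest = dists.argmin(axis=1)
        mind = dists[np.arange(len(pts)), nearest]
        snapped = np.where(nearest < 3, nearest + 1, CENTER).astype(np.int8)
        ok = mind <= geometry.snap_tolerance_cm
        if (~ok).any() and on_outside == "raise":
            bad = safe_xy[unresolved][~ok][0]
            raise OutOfArenaError(
                f"position ({bad[0]:.2f}, {bad[1]:.2f}) cm is "
                f"{mind[~ok][0]:.2f} cm outside every maze region "
                f"(tolerance {geometry.snap_tolerance_cm} cm)"
            )
        result = np.where(ok, snapped, OUTSIDE).astype(np.int8)
        codes[unresolved] = result

    codes[missing] = MISSING
    return codes


def point_to_region(x: float, y: float, geometry: MazeGeometry) -> int:
    """Classify one point (cm); see :func:`points_to_regions`."""
    return int(points_to_regions(np.array([[x, y]]), geometry)[0])


def arm_entry_depth(xy: np.ndarray, arm_codes: np.ndarray, geometry: MazeGeometry) -> np.ndarray:
    """Distance (cm) past the triangle side along each point's arm axis.

    NaN where the code is not an arm. Used to order same-frame arm entries:
    at equal swimming speed, the fish deeper into the arm crossed earlier.
    """
    xy = np.asarray(xy, dtype=float)
    depth = np.full(xy.shape[0], np.nan)
    for k in ARM_CODES:
        mask = arm_codes == k
        if mask.any():
            depth[mask] = xy[mask] @ geometry.arm_axes[k - 1] - geometry.apothem
    return depth
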
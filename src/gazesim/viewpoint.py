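"""Gaze geometry: from place, head direction and eye direction to a field of view.

The allocentric gaze is the sum of the allocentric head direction and the
egocentric eye direction, per axis (heading in the horizontal plane,
measured counter-clockwise from +x and wrapped to (-pi, pi]; elevation
above the horizontal).  Each eye carries a uniformly spaced retinal array
behind a pinhole lens: every cell is a (position, preferred incidence
direction) tuple, and the preferred directions span a uniform angular grid
centred on the optical axis.  Uniform spacing is a foveal simplification —
the fall-off of receptor density with eccentricity is deliberately ignored.

The two eyes sit half an interocular baseline to either side of the head
position, perpendicular to the head heading, and their gaze headings are
split symmetrically by the convergence angle omega.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = [
    "HeadPose",
    "EyeDirection",
    "RetinalArray",
    "EyeView",
    "FieldOfView",
    "wrap_angle",
    "direction_from_angles",
    "allocentric_gaze",
    "build_retinal_array",
    "field_of_view",
    "DEFAULT_BASELINE",
]

#: default interocular distance (m); set to 0 for a cyclopean viewer.
DEFAULT_BASELINE = 0.06


def wrap_angle(x: float) -> float:
    """Wrap an angle to the interval (-pi, pi]."""
    return float(-((-np.asarray(x) + np.pi) % (2.0 * np.pi) - np.pi))


def direction_from_angles(heading: float, elevation: float) -> np.ndarray:
    """Unit vector for a (heading, elevation) pair, z up, heading CCW from +x."""
    ce = math.cos(elevation)
    return np.array([ce * math.cos(heading), ce * math.sin(heading), math.sin(elevation)])


@dataclass(frozen=True)
class HeadPose:
    """Allocentric head position (m) and direction (heading, elevation)."""

    place: Tuple[float, float, float]
    head_dir: Tuple[float, float]

    def __post_init__(self) -> None:
        place = np.asarray(self.place, dtype=float)
        if place.shape != (3,) or not np.all(np.isfinite(place)):
            raise ValueError("place must be a finite 3-vector")
        h, e = self.head_dir
        if not (np.isfinite(h) and np.isfinite(e)):
            raise ValueError("head_dir must be finite")
        object.__setattr__(self, "place", tuple(float(x) for x in place))
        object.__setattr__(self, "head_dir", (wrap_angle(h), float(e)))


@dataclass(frozen=True)
class EyeDirection:
    """Egocentric eye direction (heading, elevation) and convergence angle."""

    ego_dir: Tuple[float, float] = (0.0, 0.0)
    convergence: float = 0.0

    def __post_init__(self) -> None:
        h, e = self.ego_dir
        if abs(h) >= math.pi / 2 or abs(e) >= math.pi / 2:
            raise ValueError("egocentric eye direction components must be < pi/2")
        if self.convergence < 0:
            raise ValueError("convergence must be non-negative")


@dataclass(frozen=True)
class RetinalArray:
    """Uniform angular grid of retinal cells behind a pinhole lens.

    Row offsets run from +extent/2 (top) to -extent/2 (bottom) in
    elevation; column offsets from +extent/2 (viewer's left, since heading
    is CCW-positive) to -extent/2 (right).  A single-cell axis sits on the
    optical axis.
    """

    n_rows: int
    n_cols: int
    angular_extent: float
    elevation_offsets: np.ndarray
    heading_offsets: np.ndarray

    def local_directions(self) -> np.ndarray:
        """(n_rows, n_cols, 3) preferred-incidence unit vectors, optical axis +x."""
        e = self.elevation_offsets[:, None]
        h = self.heading_offsets[None, :]
        ce = np.cos(e)
        return np.stack(
            [
                np.broadcast_to(ce * np.cos(h), (self.n_rows, self.n_cols)),
                np.broadcast_to(ce * np.sin(h), (self.n_rows, self.n_cols)),
                np.broadcast_to(np.sin(e) * np.ones_like(h), (self.n_rows, self.n_cols)),
            ],
            axis=-1,
        )

    def cell_positions(self) -> np.ndarray:
        """Cell positions relative to the lens: unit distance along each direction."""
        return self.local_directions()


def build_retinal_array(n_rows: int, n_cols: int, angular_extent: float) -> RetinalArray:
    """Uniform angular grid spanning ``angular_extent`` on both axes.

    Grid endpoints sit at +-extent/2, so corner cells are exactly half the
    extent off the optical axis; a 1-wide axis collapses onto the axis.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("n_rows and n_cols must be >= 1")
    if not 0.0 < angular_extent < math.pi:
        raise ValueError(f"angular_extent must be in (0, pi), got {angular_extent}")

    def offsets(n: int) -> np.ndarray:
        if n == 1:
            return np.zeros(1)
        return np.linspace(angular_extent / 2.0, -angular_extent / 2.0, n)

    return RetinalArray(
        n_rows=int(n_rows),
        n_cols=int(n_cols),
        angular_extent=float(angular_extent),
        elevation_offsets=offsets(n_rows),
        heading_offsets=offsets(n_cols),
    )


def allocentric_gaze(head_dir: Tuple[float, float],
                     ego_dir: Tuple[float, float]) -> Tuple[float, float]:
    """Allocentric gaze = head direction + egocentric eye direction.

    The heading component is wrapped to (-pi, pi]; elevation is an
    unwrapped sum (it stays well inside (-pi/2, pi/2) for valid inputs).
    """
    return (wrap_angle(head_dir[0] + ego_dir[0]), head_dir[1] + ego_dir[1])


@dataclass(frozen=True)
class EyeView:
    """One eye's lens origin, allocentric gaze, and oriented cell directions."""

    origin: np.ndarray
    gaze: Tuple[float, float]
    directions: np.ndarray  # (n_rows, n_cols, 3) world-frame unit vectors


@dataclass(frozen=True)
class FieldOfView:
    left: EyeView
    right: EyeView
    array: RetinalArray


def _orient(array: RetinalArray, gaze: Tuple[float, float]) -> np.ndarray:
    gh, ge = gaze
    e = ge + array.elevation_offsets[:, None]
    h = gh + array.heading_offsets[None, :]
    ce = np.cos(e)
    shape = (array.n_rows, array.n_cols)
    return np.stack(
        [
            np.broadcast_to(ce * np.cos(h), shape),
            np.broadcast_to(ce * np.sin(h), shape),
            np.broadcast_to(np.sin(e) * np.ones_like(h), shape),
        ],
        axis=-1,
    )


def field_of_view(pose: HeadPose, eyes: EyeDirection, array: RetinalArray,
                  baseline: float = DEFAULT_BASELINE) -> FieldOfView:
    """Binocular field of view from pose, eye direction and a retinal array.

    The eyes sit at the head position offset by half the baseline along the
    lateral axis (perpendicular to the head heading); the left eye's gaze
    heading is the allocentric gaze plus omega/2, the right eye's minus
    omega/2, so the headings differ by exactly the convergence angle while
    sharing elevation.
    """
    gaze = allocentric_gaze(pose.head_dir, eyes.ego_dir)
    omega = eyes.convergence
    head_h = pose.head_dir[0]
    lateral = np.array([-math.sin(head_h), math.cos(head_h), 0.0])  # viewer's left
    place = np.asarray(pose.place, dtype=float)

    left_gaze = (gaze[0] + omega / 2.0, gaze[1])
    right_gaze = (gaze[0] - omega / 2.0, gaze[1])
    left = EyeView(place + (baseline / 2.0) * lateral, left_gaze, _orient(array, left_gaze))
    right = EyeView(place - (baseline / 2.0) * lateral, right_gaze, _orient(array, right_gaze))
    return FieldOfView(left=left, right=right, array=array)
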
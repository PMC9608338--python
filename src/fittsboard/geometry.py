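"""Hexagonal honeycomb grid geometry and angular binning of cursor movements.

Keys are pointy-top hexagons in an odd-r offset layout: odd rows are shifted
right by half a key width and consecutive rows are ``W * sqrt(3)/2`` apart,
so adjacent keys sit exactly one key width ``W`` apart center-to-center.
The default grid is 9 x 9 with 130-px keys, matching a 1080-px-tall display.

Pixel coordinates follow the screen convention (x grows rightward, y grows
downward).  Selection angles, however, are reported the way the user
experiences them: 0 degrees is a rightward movement and 90 degrees is upward
on screen, i.e. the screen y-axis is flipped before computing the angle.
Directions are discretized into 16 bins of 22.5 degrees each, centered on
the cardinal, intercardinal and half-wind directions, so direction-specific
movement models can be fitted per bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridSpec",
    "KeyPosition",
    "AngularBinScheme",
    "key_center",
    "selection_angle",
    "bin_of",
    "index_of_difficulty",
    "euclidean",
]

_ROW_SPACING = math.sqrt(3.0) / 2.0  # vertical pitch of a pointy-top hex row, in key widths


@dataclass(frozen=True)
class KeyPosition:
    """One key of the grid: 0-based (row, col) plus its pixel center."""

    row: int
    col: int
    center: tuple[float, float]

    def __iter__(self):
        yield self.row
        yield self.col


@dataclass(frozen=True)
class GridSpec:
    """Honeycomb grid of hexagonal keys.

    ``key_width_px`` is the horizontal center-to-center spacing W, which is
    also the target width used in the index-of-difficulty computation.
    ``origin`` is the pixel center of the top-left key (row 0, col 0).
    """

    rows: int = 9
    cols: int = 9
    key_width_px: float = 130.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.key_width_px <= 0:
            raise ValueError("key_width_px must be positive")

    def key(self, row: int, col: int) -> KeyPosition:
        return KeyPosition(row, col, key_center(self, row, col))

    def all_keys(self) -> list[KeyPosition]:
        return [self.key(r, c) for r in range(self.rows) for c in range(self.cols)]

    def center_key(self) -> KeyPosition:
        """The key closest to the middle of the index grid (rows//2, cols//2)."""
        return self.key(self.rows // 2, self.cols // 2)

    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "cols": self.cols,
            "key_width_px": self.key_width_px,
            "origin": list(self.origin),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(
            rows=int(d["rows"]),
            cols=int(d["cols"]),
            key_width_px=float(d["key_width_px"]),
            origin=tuple(float(v) for v in d.get("origin", (0.0, 0.0))),
        )


def key_center(grid: GridSpec, row: int, col: int) -> tuple[float, float]:
    """Pixel center of the key at (row, col) in odd-r offset coordinates.

    Odd rows shift right by W/2; row pitch is W*sqrt(3)/2.

    Raises
    ------
    IndexError
        If (row, col) lies outside the grid.
    """
    if not (0 <= row < grid.rows and 0 <= col < grid.cols):
        raise IndexError(f"key ({row}, {col}) outside {grid.rows}x{grid.cols} grid")
    w = grid.key_width_px
    x = grid.origin[0] + col * w + (w / 2.0 if row % 2 == 1 else 0.0)
    y = grid.origin[1] + row * w * _ROW_SPACING
    return (x, y)


def euclidean(p: tuple[float, float], q: tuple[float, float]) -> float:
    return math.hypot(q[0] - p[0], q[1] - p[1])


def selection_angle(p_from: tuple[float, float], p_to: tuple[float, float]) -> float:
    """Direction of the movement from ``p_from`` to ``p_to``, in degrees.

    User-facing convention: 0 = rightward, 90 = upward *on screen*.  Because
    pixel y grows downward, the y displacement is negated before atan2.
    Result lies in [0, 360).

    Raises
    ------
    ValueError
        If the two points coincide (a zero-distance move has no direction).
    """
    dx = p_to[0] - p_from[0]
    dy = p_to[1] - p_from[1]
    if dx == 0.0 and dy == 0.0:
        raise ValueError("selection angle undefined for identical points")
    ang = math.degrees(math.atan2(-dy, dx))
    return ang % 360.0


@dataclass(frozen=True)
class AngularBinScheme:
    """Partition of [0, 360) into equal arcs centered on bin-center angles.

    Bin 0 is centered on 0 degrees (rightward); bins proceed counter-clockwise
    in the user-facing convention.  With the default 16 bins each arc spans
    22.5 degrees: the four cardinals, four intercardinals and eight
    half-winds each own one symmetric arc.
    """

    n_bins: int = 16

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("need at least one angular bin")

    @property
    def bin_width_deg(self) -> float:
        return 360.0 / self.n_bins

    @property
    def centers_deg(self) -> list[float]:
        return [k * self.bin_width_deg for k in range(self.n_bins)]

    def circular_bin_distance(self, i: int, j: int) -> int:
        d = abs(i - j) % self.n_bins
        return min(d, self.n_bins - d)

    def to_dict(self) -> dict:
        return {"n_bins": self.n_bins}

    @classmethod
    def from_dict(cls, d: dict) -> "AngularBinScheme":
        return cls(n_bins=int(d["n_bins"]))


def bin_of(angle_deg: float, scheme: AngularBinScheme = AngularBinScheme()) -> int:
    """Index of the bin whose arc contains ``angle_deg``.

    Bin k covers the half-open arc [center - width/2, center + width/2),
    wrapping through 360 for bin 0.
    """
    w = scheme.bin_width_deg
    return int(math.floor((angle_deg % 360.0) / w + 0.5)) % scheme.n_bins


def index_of_difficulty(distance_px: float, key_width_px: float) -> float:
    """Shannon-formulation Fitts index of difficulty, log2(D/W + 1), in bits.

    Zero exactly when D = 0 and strictly increasing in D.

    Raises
    ------
    ValueError
        If the distance is negative or the width nonpositive.
    """
    if distance_px < 0:
        raise ValueError("distance must be nonnegative")
    if key_width_px <= 0:
        raise ValueError("key width must be positive")
    return math.log2(distance_px / key_width_px + 1.0)
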
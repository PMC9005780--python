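"""Planar cross-section container and resampling helpers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from shapely.geometry import Polygon

from .errors import GeometryError


def _close_loop(points: np.ndarray) -> np.ndarray:
    if np.allclose(points[0], points[-1]):
        return points
    return np.vstack([points, points[0]])


def resample_closed_curve(points: np.ndarray, n: int = 360) -> np.ndarray:
    """Resample an ordered closed curve to n points, uniform in arc length."""
    pts = _close_loop(np.asarray(points, dtype=float))
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise GeometryError("degenerate curve with zero perimeter")
    si = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(si, s, pts[:, 0])
    y = np.interp(si, s, pts[:, 1])
    return np.column_stack([x, y])


def ensure_ccw(points: np.ndarray) -> np.ndarray:
    """Order a closed curve counter-clockwise (positive signed area)."""
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    area2 = np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
    return pts if area2 >= 0 else pts[::-1]


@dataclass
class CrossSection:
    """Closed planar curve (nm), ordered counter-clockwise.

    Optional 2.5/97.5 percentile curves bracket the mean curve when the
    section was averaged over axial samples; ``axis_xy`` marks the screw
    axis position in the section plane.
    """

    points: np.ndarray
    lower: Optional[np.ndarray] = None
    upper: Optional[np.ndarray] = None
    axis_xy: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.points = ensure_ccw(np.asarray(self.points, dtype=float))
        if len(self.points) < 3:
            raise GeometryError("cross-section needs at least 3 points")
        self.axis_xy = np.asarray(self.axis_xy, dtype=float)

    def polygon(self) -> Polygon:
        poly = Polygon(self.points)
        if not poly.is_valid:
            raise GeometryError("self-intersecting cross-section curve")
        return poly

    @property
    def centroid(self) -> np.ndarray:
        c = self.polygon().centroid
        return np.array([c.x, c.y])

    def resampled(self, n: int = 360) -> "CrossSection":
        return CrossSection(
            points=resample_closed_curve(self.points, n),
            lower=None if self.lower is None else resample_closed_curve(self.lower, n),
            upper=None if self.upper is None else resample_closed_curve(self.upper, n),
            axis_xy=self.axis_xy,
        )

    def centred(self) -> "CrossSection":
        c = self.centroid
        return CrossSection(
            points=self.points - c,
            lower=None if self.lower is None else self.lower - c,
            upper=None if self.upper is None else self.upper - c,
            axis_xy=self.axis_xy - c,
        )

    def rotated(self, angle_deg: float) -> "CrossSection":
        a = np.deg2rad(angle_deg)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        return CrossSection(
            points=self.points @ rot.T,
            lower=None if self.lower is None else self.lower @ rot.T,
            upper=None if self.upper is None else self.upper @ rot.T,
            axis_xy=rot @ self.axis_xy,
        )

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.points, columns=["x_nm", "y_nm"])
        if self.lower is not None and len(self.lower) == len(self.points):
            df["x_lo_nm"], df["y_lo_nm"] = self.lower[:, 0], self.lower[:, 1]
            df["x_hi_nm"], df["y_hi_nm"] = self.upper[:, 0], self.upper[:, 1]
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CrossSection":
        import pandas as pd

        df = pd.read_csv(path)
        lower = upper = None
        if "x_lo_nm" in df:
            lower = df[["x_lo_nm", "y_lo_nm"]].to_numpy()
            upper = df[["x_hi_nm", "y_hi_nm"]].to_numpy()
        return cls(points=df[["x_nm", "y_nm"]].to_numpy(), lower=lower, upper=upper)
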
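"""Cross-section morphometrics: tip-accessible boundaries, rotational
alignment, cross-sectional area (csa) and difference area (csd).

The tip-accessible boundary of a cross-section point cloud is its 2D
alpha shape with alpha radius equal to the AFM tip radius: concavities
narrower than the probe cannot be reached and are bridged over, which
makes cross-sections derived from cryo-EM maps directly comparable with
those reconstructed from AFM topographs.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree
from shapely.geometry import Polygon

from .errors import GeometryError
from .sections import CrossSection, resample_closed_curve


def _circumradius(pa: np.ndarray, pb: np.ndarray, pc: np.ndarray) -> np.ndarray:
    """Circumradius of triangles given vertex arrays (vectorised)."""
    a = np.linalg.norm(pb - pc, axis=1)
    b = np.linalg.norm(pa - pc, axis=1)
    c = np.linalg.norm(pa - pb, axis=1)
    cross = (pb[:, 0] - pa[:, 0]) * (pc[:, 1] - pa[:, 1]) - (
        pb[:, 1] - pa[:, 1]
    ) * (pc[:, 0] - pa[:, 0])
    area = 0.5 * np.abs(cross)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = a * b * c / (4.0 * area)
    r[area <= 1e-300] = np.inf
    return r


def _boundary_rings(edges: List[Tuple[int, int]], points: np.ndarray) -> List[np.ndarray]:
    """Assemble undirected boundary edges into closed vertex rings."""
    adj: dict[int, list[int]] = {}
    for i, j in edges:
        adj.setdefault(i, []).append(j)
        adj.setdefault(j, []).append(i)
    unused = {tuple(sorted(e)) for e in edges}
    rings = []
    while unused:
        start = next(iter(unused))
        ring = [start[0], start[1]]
        unused.discard(start)
        while True:
            cur, prev = ring[-1], ring[-2]
            nxt = None
            for cand in adj.get(cur, []):
                if cand != prev and tuple(sorted((cur, cand))) in unused:
                    nxt = cand
                    break
            if nxt is None:
                break
            unused.discard(tuple(sorted((cur, nxt))))
            if nxt == ring[0]:
                break
            ring.append(nxt)
        if len(ring) >= 3:
            rings.append(np.asarray(ring))
    return rings


def alpha_shape_2d(points: np.ndarray, alpha_radius: float) -> np.ndarray:
    """Boundary of the 2D alpha shape of a point cloud.

    Keeps Delaunay triangles with circumradius < alpha_radius and walks
    the edges that belong to exactly one kept triangle; the outer ring
    (largest enclosed area) is returned, which also suppresses interior
    holes.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise GeometryError("need at least 3 points for an alpha shape")
    try:
        tri = Delaunay(points)
    except QhullError as exc:
        raise GeometryError(f"degenerate point cloud: {exc}") from exc
    simplices = tri.simplices
    pa, pb, pc = (points[simplices[:, k]] for k in range(3))
    keep = _circumradius(pa, pb, pc) < alpha_radius
    if not keep.any():
        raise GeometryError(
            f"alpha radius {alpha_radius} too small: no triangles retained"
        )
    edge_count: dict[Tuple[int, int], int] = {}
    for s in simplices[keep]:
        for i, j in ((s[0], s[1]), (s[1], s[2]), (s[0], s[2])):
            e = (min(i, j), max(i, j))
            edge_count[e] = edge_count.get(e, 0) + 1
    boundary = [e for e, c in edge_count.items() if c == 1]
    rings = _boundary_rings(boundary, points)
    if not rings:
        raise GeometryError("alpha shape produced no closed boundary")
    areas = [abs(Polygon(points[r]).area) for r in rings]
    return points[rings[int(np.argmax(areas))]]


def tip_accessible_boundary(
    points_2d: np.ndarray, tip_radius_nm: float, n_resample: int = 360
) -> CrossSection:
    """Tip-accessible cross-section: alpha shape with alpha = tip radius."""
    if len(points_2d) < 10:
        raise GeometryError("need at least 10 points")
    if tip_radius_nm <= 0:
        raise ValueError("tip_radius_nm must be > 0")
    ring = alpha_shape_2d(points_2d, tip_radius_nm)
    return CrossSection(points=resample_closed_curve(ring, n_resample))


def _sym_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric point-to-nearest-point RMSD between two curves."""
    da, _ = cKDTree(b).query(a)
    db, _ = cKDTree(a).query(b)
    return float(np.sqrt((np.sum(da**2) + np.sum(db**2)) / (len(a) + len(b))))


def align_cross_sections(
    cs_a: CrossSection, cs_b: CrossSection, n_points: int = 360
) -> Tuple[float, float]:
    """Best rotational alignment of two centred cross-sections.

    Both curves are resampled to ``n_points`` by arc length and centred
    on their centroids; cs_a is rotated in 1 degree steps over a full
    turn and the symmetric point-to-nearest-point RMSD to cs_b evaluated
    at each.  Returns (best_angle_deg, rmsd_nm), where the angle is the
    rotation applied to cs_a; ties break to the smallest angle.
    """
    a = cs_a.resampled(n_points).centred().points
    b = cs_b.resampled(n_points).centred().points
    best_angle, best_rmsd = 0.0, np.inf
    for ang in range(360):
        t = np.deg2rad(ang)
        rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        r = _sym_rmsd(a @ rot.T, b)
        if r < best_rmsd - 1e-12:
            best_rmsd, best_angle = r, float(ang)
    return best_angle, best_rmsd


def cross_section_area(cs: CrossSection) -> float:
    """Enclosed polygon area in nm^2 (shoelace)."""
    return float(cs.polygon().area)


def cross_section_difference(
    cs_a: CrossSection, cs_b: CrossSection, prealigned: bool = False
) -> float:
    """Symmetric-difference area of the two enclosed regions (nm^2).

    Unless ``prealigned``, curves are first centred on their centroids
    and cs_b rotated to the best 1 degree alignment.
    """
    a, b = cs_a, cs_b
    if not prealigned:
        a, b = a.centred(), b.centred()
        angle, _ = align_cross_sections(a, b)
        a = a.rotated(angle)
    pa, pb = a.polygon(), b.polygon()
    return float(pa.union(pb).area - pa.intersection(pb).area)
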
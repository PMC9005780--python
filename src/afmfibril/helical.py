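"""Screw-axis fitting and helical coordinate operations.

A helical filament maps onto itself under the screw operation
(rotation by the twist about its axis plus translation by the rise
along it).  The axis position is recovered by maximising the overlap
between a voxelised iso-surface and its helically transformed copy;
cross-sections are obtained by untwisting all vertices into one plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .errors import NoAxisFoundError
from .map_io import HelicalParams, SurfaceCloud


@dataclass
class ScrewAxisPose:
    """Fitted screw-axis position/direction relative to the input frame.

    offset_xy: axis position in the cross-sectional plane (nm);
    tilt_deg: small residual rotations about x and y (deg);
    overlap_score: hard Jaccard overlap of the voxelised surface with its
    screw-transformed copy at the optimum.
    """

    offset_xy: np.ndarray
    tilt_deg: np.ndarray
    overlap_score: float


def _rot_z(points: np.ndarray, angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    out = points.copy()
    out[:, 0] = c * points[:, 0] - s * points[:, 1]
    out[:, 1] = s * points[:, 0] + c * points[:, 1]
    return out


def screw_transform(
    points: np.ndarray, helical: HelicalParams, repeats: int = 1
) -> np.ndarray:
    """Apply the screw operation (twist about z, rise along z) ``repeats`` times."""
    out = _rot_z(points, np.deg2rad(helical.twist_deg) * repeats)
    out[:, 2] += helical.rise_nm * repeats
    return out


def _apply_pose(points: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Shift by -(dx, dy) and tilt so the candidate axis becomes the z-axis."""
    dx, dy, tx, ty = params
    pts = points - np.array([dx, dy, 0.0])
    ax, ay = np.deg2rad(tx), np.deg2rad(ty)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    return pts @ (ry @ rx).T


def _splat(points: np.ndarray, lo: np.ndarray, shape: Tuple[int, int, int], voxel: float) -> np.ndarray:
    """Trilinear scatter of points into a density grid (continuous in pose)."""
    grid = np.zeros(shape)
    f = (points - lo) / voxel
    i0 = np.floor(f).astype(np.int64)
    w = f - i0
    nx, ny, nz = shape
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                wgt = (
                    (w[:, 0] if dx else 1 - w[:, 0])
                    * (w[:, 1] if dy else 1 - w[:, 1])
                    * (w[:, 2] if dz else 1 - w[:, 2])
                )
                ix, iy, iz = i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz
                ok = (
                    (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & (iz >= 0) & (iz < nz)
                )
                np.add.at(grid, (ix[ok], iy[ok], iz[ok]), wgt[ok])
    return grid


def _occupied(points: np.ndarray, voxel: float) -> np.ndarray:
    """1D-hashed set of occupied voxel indices."""
    idx = np.floor(points / voxel).astype(np.int64)
    return np.unique(
        (idx[:, 0] + 2**20) + (idx[:, 1] + 2**20) * 2**21 + (idx[:, 2] + 2**20) * 2**42
    )


def _hard_jaccard(a: np.ndarray, b: np.ndarray, voxel: float) -> float:
    sa, sb = _occupied(a, voxel), _occupied(b, voxel)
    inter = np.intersect1d(sa, sb, assume_unique=True).size
    union = sa.size + sb.size - inter
    return inter / union if union else 0.0


def _amplified_repeats(helical: HelicalParams, z_extent: float, target_deg: float = 90.0) -> int:
    """Compose the screw op enough times to accumulate ~target_deg of twist.

    A single small-twist op is nearly a pure z-shift and carries little
    information about the axis position.  The repeat count is capped so
    the z-shift stays below 40% of the segment length.
    """
    cap = max(1, int(0.4 * z_extent / helical.rise_nm))
    if helical.twist_deg == 0:
        return cap
    k = int(round(target_deg / abs(helical.twist_deg)))
    return int(np.clip(k, 1, cap))


def fit_screw_axis(
    surface: SurfaceCloud,
    helical: HelicalParams,
    mode: str = "joint",
    voxel_nm: float | None = None,
) -> Tuple[SurfaceCloud, ScrewAxisPose]:
    """Locate the screw axis and re-centre the surface onto it.

    The objective is the overlap between the voxelised surface and its
    screw-transformed copy, evaluated on their common z-window.  The
    continuous optimisation uses a trilinear-splat (fuzzy) Jaccard,
    sum(min)/sum(max) of the two occupancy grids, which is smooth in the
    pose parameters; the returned ``overlap_score`` is the hard voxel
    Jaccard at the optimum.  ``mode='staged'`` optimises tilt, then
    translation, then polishes jointly.
    """
    if mode not in ("joint", "staged"):
        raise ValueError(f"mode must be 'joint' or 'staged', got {mode!r}")
    if voxel_nm is None:
        voxel_nm = surface.voxel_size
    if voxel_nm is None:
        raise ValueError("voxel_nm not given and surface has no voxel_size")

    verts = surface.vertices - surface.vertices.mean(axis=0)
    reps = _amplified_repeats(helical, float(np.ptp(verts[:, 2])))

    zlo = verts[:, 2].min() + reps * helical.rise_nm
    zhi = verts[:, 2].max()

    def common_window(a: np.ndarray, b: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        return (
            a[(a[:, 2] >= zlo) & (a[:, 2] <= zhi)],
            b[(b[:, 2] >= zlo) & (b[:, 2] <= zhi)],
        )

    def fuzzy_neg(params: np.ndarray) -> float:
        pts = _apply_pose(verts, params)
        a, b = common_window(pts, screw_transform(pts, helical, reps))
        if len(a) < 4 or len(b) < 4:
            return 0.0
        allp = np.vstack([a, b])
        lo = allp.min(axis=0) - voxel_nm
        shape = tuple(
            int(np.ceil((allp[:, i].max() - lo[i]) / voxel_nm)) + 2 for i in range(3)
        )
        ga, gb = _splat(a, lo, shape, voxel_nm), _splat(b, lo, shape, voxel_nm)
        num = np.minimum(ga, gb).sum()
        den = np.maximum(ga, gb).sum()
        return -num / den if den else 0.0

    # coarse grid over xy offsets (centre-of-mass start can sit well off
    # the screw axis for sections whose centroid != axis)
    span = np.arange(-2.0, 2.01, 1.0) * voxel_nm
    x0 = np.zeros(4)
    best = np.inf
    for ox in span:
        for oy in span:
            v = fuzzy_neg(np.array([ox, oy, 0.0, 0.0]))
            if v < best:
                best, x0 = v, np.array([ox, oy, 0.0, 0.0])

    def simplex(centre: np.ndarray, steps: Sequence[float]) -> np.ndarray:
        sim = np.tile(centre, (len(centre) + 1, 1))
        for i, s in enumerate(steps):
            sim[i + 1, i] += s
        return sim

    if mode == "staged":
        r_tilt = minimize(
            lambda t: fuzzy_neg(np.array([x0[0], x0[1], t[0], t[1]])),
            x0[2:], method="Nelder-Mead",
            options={"xatol": 0.05, "fatol": 1e-5, "maxiter": 200,
                     "initial_simplex": simplex(x0[2:], [2.0, 2.0])},
        )
        x0[2:] = r_tilt.x
        r_off = minimize(
            lambda o: fuzzy_neg(np.array([o[0], o[1], x0[2], x0[3]])),
            x0[:2], method="Nelder-Mead",
            options={"xatol": 0.02, "fatol": 1e-5, "maxiter": 200,
                     "initial_simplex": simplex(x0[:2], [voxel_nm, voxel_nm])},
        )
        x0[:2] = r_off.x
    res = minimize(
        fuzzy_neg, x0, method="Nelder-Mead",
        options={"xatol": 0.01, "fatol": 1e-6, "maxiter": 400,
                 "initial_simplex": simplex(x0, [voxel_nm, voxel_nm, 1.0, 1.0])},
    )
    params = res.x

    pts = _apply_pose(verts, params)
    a, b = common_window(pts, screw_transform(pts, helical, reps))
    score = _hard_jaccard(a, b, voxel_nm) if len(a) >= 4 and len(b) >= 4 else 0.0
    if score < 0.5:
        raise NoAxisFoundError(
            f"screw-axis overlap {score:.3f} < 0.5; map and helical metadata "
            "are likely inconsistent"
        )
    pose = ScrewAxisPose(
        offset_xy=params[:2].copy() + surface.vertices.mean(axis=0)[:2],
        tilt_deg=params[2:].copy(),
        overlap_score=score,
    )
    recentred = surface.replace(vertices=pts, helical=helical)
    return recentred, pose


def extend_helical(
    surface: SurfaceCloud,
    helical: HelicalParams,
    target_length_nm: float,
    dedup_tol_voxel: float = 0.25,
) -> SurfaceCloud:
    """Helically extend a segment along +z until it spans target_length_nm.

    Copies of the segment are placed at successive multiples of
    (twist, rise); vertices landing within ``dedup_tol_voxel`` voxels of
    an existing vertex are dropped (seam deduplication).
    """
    if helical.rise_nm <= 0:
        raise ValueError("rise must be > 0")
    verts = surface.vertices
    z0 = verts[:, 2].max() - verts[:, 2].min()
    if target_length_nm <= z0:
        return surface
    n_copies = int(np.ceil((target_length_nm - z0) / helical.rise_nm))
    blocks = [verts]
    for k in range(1, n_copies + 1):
        blocks.append(screw_transform(verts, helical, k))
    allv = np.vstack(blocks)
    if dedup_tol_voxel > 0 and surface.voxel_size:
        cell = dedup_tol_voxel * surface.voxel_size
        key = np.floor(allv / cell).astype(np.int64)
        hashed = (key[:, 0] + 2**20) + (key[:, 1] + 2**20) * 2**21 + (key[:, 2] + 2**20) * 2**42
        _, keep = np.unique(hashed, return_index=True)
        allv = allv[np.sort(keep)]
    return surface.replace(vertices=allv, faces=None, helical=helical)


def untwist_to_plane(surface: SurfaceCloud, helical: HelicalParams) -> np.ndarray:
    """Rotate every vertex back by the accumulated twist and project to xy.

    Returns the rotational cross-section of the filament as an (N, 2)
    point cloud (nm) about the screw axis at the origin.
    """
    verts = surface.vertices
    theta = -helical.omega_rad_per_nm * verts[:, 2]
    c, s = np.cos(theta), np.sin(theta)
    x = c * verts[:, 0] - s * verts[:, 1]
    y = s * verts[:, 0] + c * verts[:, 1]
    return np.column_stack([x, y])


def cross_section_spread(points_2d: np.ndarray, n_bins: int = 180) -> float:
    """RMS radial dispersion of an untwisted cloud within angular bins.

    Used as a sharpness figure of merit: correct helical parameters
    collapse the cloud onto a thin closed curve (small spread), wrong
    twist or handedness smears it.
    """
    r = np.hypot(points_2d[:, 0], points_2d[:, 1])
    theta = np.arctan2(points_2d[:, 1], points_2d[:, 0])
    bins = np.floor((theta + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
    tot, cnt = np.zeros(n_bins), np.zeros(n_bins)
    np.add.at(tot, bins, r)
    np.add.at(cnt, bins, 1.0)
    mean_r = np.where(cnt > 0, tot / np.maximum(cnt, 1), 0.0)
    var = np.zeros(n_bins)
    np.add.at(var, bins, (r - mean_r[bins]) ** 2)
    good = cnt > 1
    if not good.any():
        return 0.0
    return float(np.sqrt((var[good] / cnt[good]).mean()))
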
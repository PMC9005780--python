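"""AFM tip model and geometric contact-imaging simulation.

An AFM topograph of a rigid surface is the grey-scale dilation of the
surface's top height function by the reflected tip: at each pixel the
recorded height is the highest position at which the tip, lowered
vertically, first touches the sample,

    image(x) = max_p [ p_z - tip_z(|x - p_xy|) ],

over all surface points p, clipped at the substrate (0).  The tip is a
sphere-capped cone, tangent-continuous at the sphere/cone junction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

from .errors import BoundaryWarning, EmptySurfaceError, EstimationWarning, UndefinedScoreError
from .map_io import SurfaceCloud

try:  # numba accelerates the per-point stamping loops; numpy fallback is exact too
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@dataclass
class TipModel:
    """Sphere-capped cone probe, apex at the origin, opening upward.

    radius_nm: apex sphere radius; half_angle_deg: cone half-angle from
    the vertical axis.  The sphere-to-cone transition at lateral distance
    d_t = R cos(alpha) is tangent-continuous.
    """

    radius_nm: float
    half_angle_deg: float = 18.0

    def __post_init__(self) -> None:
        if not self.radius_nm > 0:
            raise ValueError(f"radius_nm must be > 0, got {self.radius_nm}")
        if not 0 < self.half_angle_deg < 90:
            raise ValueError(
                f"half_angle_deg must be in (0, 90), got {self.half_angle_deg}"
            )

    @property
    def _alpha(self) -> float:
        return np.deg2rad(self.half_angle_deg)

    @property
    def transition_d(self) -> float:
        """Lateral distance of the tangent sphere/cone junction."""
        return self.radius_nm * np.cos(self._alpha)

    @property
    def transition_z(self) -> float:
        return self.radius_nm * (1.0 - np.sin(self._alpha))

    @property
    def cot_alpha(self) -> float:
        return 1.0 / np.tan(self._alpha)

    def z(self, d):
        """Tip surface height above the apex at lateral distance d (nm)."""
        d = np.asarray(d, dtype=float)
        r = self.radius_nm
        sphere = r - np.sqrt(np.maximum(r * r - np.minimum(d, self.transition_d) ** 2, 0.0))
        cone = self.transition_z + (d - self.transition_d) * self.cot_alpha
        return np.where(d <= self.transition_d, sphere, cone)

    def reach(self, h):
        """Lateral distance at which the tip flank sits at height h."""
        h = np.asarray(h, dtype=float)
        r = self.radius_nm
        in_cap = h <= self.transition_z
        cap = np.sqrt(np.maximum(h, 0.0) * np.maximum(2 * r - h, 0.0))
        cone = self.transition_d + (h - self.transition_z) * np.tan(self._alpha)
        return np.where(in_cap, cap, cone)


def build_tip(radius_nm: float, half_angle_deg: float = 18.0) -> TipModel:
    """Construct a sphere-capped cone tip from manufacturer geometry."""
    return TipModel(radius_nm=radius_nm, half_angle_deg=half_angle_deg)


@dataclass
class HeightMap:
    """2D raster of surface heights (nm), substrate at 0.

    heights[iy, ix]: pixel centre at (x0 + ix*px, y0 + iy*px).  The
    fibril axis runs along the image y-axis (axis 0).
    """

    heights: np.ndarray
    pixel_size_nm: float
    axis_height_nm: Optional[float] = None
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be 2D")
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be > 0")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.heights.shape


# --------------------------------------------------------------------------
# contact-point stamping kernels

@njit(cache=True)
def _stamp_max(px, py, pz, img, pixel, x0, y0, r_t, z_t, cot, radius):
    ny, nx = img.shape
    for n in range(px.size):
        h = pz[n]
        if h <= 0.0:
            continue
        # lateral reach of the tip flank at height h
        if h <= z_t:
            rmax = np.sqrt(max(h, 0.0) * max(2.0 * radius - h, 0.0))
        else:
            rmax = r_t + (h - z_t) / cot
        i_lo = max(int(np.ceil((py[n] - rmax - y0) / pixel)), 0)
        i_hi = min(int(np.floor((py[n] + rmax - y0) / pixel)), ny - 1)
        j_lo = max(int(np.ceil((px[n] - rmax - x0) / pixel)), 0)
        j_hi = min(int(np.floor((px[n] + rmax - x0) / pixel)), nx - 1)
        for i in range(i_lo, i_hi + 1):
            dy = y0 + i * pixel - py[n]
            for j in range(j_lo, j_hi + 1):
                dx = x0 + j * pixel - px[n]
                d = np.sqrt(dx * dx + dy * dy)
                if d <= r_t:
                    tz = radius - np.sqrt(radius * radius - d * d)
                else:
                    tz = z_t + (d - r_t) * cot
                v = h - tz
                if v > img[i, j]:
                    img[i, j] = v


@njit(cache=True)
def _erode_min(img, out, pixel, r_t, z_t, cot, radius, w):
    ny, nx = img.shape
    for i in range(ny):
        for j in range(nx):
            best = img[i, j]
            for di in range(-w, w + 1):
                ii = i + di
                if ii < 0 or ii >= ny:
                    continue
                for dj in range(-w, w + 1):
                    jj = j + dj
                    if jj < 0 or jj >= nx:
                        continue
                    d = pixel * np.sqrt(di * di + dj * dj)
                    if d <= r_t:
                        tz = radius - np.sqrt(radius * radius - d * d)
                    else:
                        tz = z_t + (d - r_t) * cot
                    v = img[ii, jj] + tz
                    if v < best:
                        best = v
            out[i, j] = best


def _densify(surface: SurfaceCloud, max_edge: float) -> np.ndarray:
    """Subdivide mesh faces until edges <= max_edge; point clouds pass through."""
    if surface.faces is None or not len(surface.faces):
        return surface.vertices
    from trimesh.remesh import subdivide_to_size

    verts, _ = subdivide_to_size(
        surface.vertices, surface.faces, max_edge=max_edge, max_iter=8
    )
    return verts


def to_image_frame(surface: SurfaceCloud, drop_to_substrate: bool = True) -> SurfaceCloud:
    """Rotate an axis-aligned surface (axis = z) into the imaging frame.

    Applies the 90 deg rotation (x, y, z) -> (x, -z, y) so the filament
    axis runs along the image y-axis, then rests the surface on the
    substrate plane z = 0.
    """
    v = surface.vertices
    out = np.column_stack([v[:, 0], -v[:, 2], v[:, 1]])
    if drop_to_substrate:
        out[:, 2] -= out[:, 2].min()
    return surface.replace(vertices=out)


def simulate_topograph(
    surface: SurfaceCloud,
    tip: TipModel,
    pixel_size_nm: float,
    grid_shape: Optional[Tuple[int, int]] = None,
    grid_origin: Optional[Tuple[float, float]] = None,
    densify: bool = True,
) -> HeightMap:
    """Simulate a topographic AFM image of a surface lying on the substrate.

    Implements the contact-point model: each pixel records the height of
    the tip apex when the probe first touches any surface point, i.e.
    grey-scale dilation of the top surface by the reflected tip.  The
    surface must already be in the imaging frame (axis along y, lowest
    point at z = 0; see :func:`to_image_frame`).

    A fixed ``grid_shape``/``grid_origin`` (nm) can be supplied so that
    simulations of different candidates share the pixel grid of an
    experimental image.
    """
    if len(surface.vertices) == 0:
        raise EmptySurfaceError("empty surface")
    pts = _densify(surface, pixel_size_nm / 2.0) if densify else surface.vertices
    zmax = pts[:, 2].max()
    margin = float(tip.reach(zmax)) + 2 * pixel_size_nm
    if grid_shape is None:
        x_lo, x_hi = pts[:, 0].min() - margin, pts[:, 0].max() + margin
        y_lo, y_hi = pts[:, 1].min(), pts[:, 1].max()
        nx = int(np.ceil((x_hi - x_lo) / pixel_size_nm)) + 1
        ny = int(np.ceil((y_hi - y_lo) / pixel_size_nm)) + 1
        x0, y0 = x_lo, y_lo
    else:
        ny, nx = grid_shape
        x0, y0 = grid_origin if grid_origin is not None else (0.0, 0.0)

    img = np.zeros((ny, nx))
    _stamp_max(
        np.ascontiguousarray(pts[:, 0]),
        np.ascontiguousarray(pts[:, 1]),
        np.ascontiguousarray(pts[:, 2]),
        img,
        float(pixel_size_nm),
        float(x0),
        float(y0),
        float(tip.transition_d),
        float(tip.transition_z),
        float(tip.cot_alpha),
        float(tip.radius_nm),
    )
    return HeightMap(heights=img, pixel_size_nm=pixel_size_nm, x0=x0, y0=y0)


def erode_topograph(img: HeightMap, tip: TipModel) -> HeightMap:
    """Grey-scale erosion by the reflected tip (tip deconvolution).

    Recovers the contact-point surface: the lower envelope of tip
    positions consistent with the recorded image.  This is the exact
    inverse of the dilation wherever the tip touched the surface.
    """
    hmax = float(img.heights.max())
    w = int(np.ceil(float(tip.reach(hmax)) / img.pixel_size_nm)) + 1
    out = np.empty_like(img.heights)
    _erode_min(
        img.heights,
        out,
        float(img.pixel_size_nm),
        float(tip.transition_d),
        float(tip.transition_z),
        float(tip.cot_alpha),
        float(tip.radius_nm),
        w,
    )
    return HeightMap(
        heights=out,
        pixel_size_nm=img.pixel_size_nm,
        axis_height_nm=img.axis_height_nm,
        x0=img.x0,
        y0=img.y0,
    )


# --------------------------------------------------------------------------
# tip radius estimation

def _dilate_profile_1d(xs: np.ndarray, px: np.ndarray, pz: np.ndarray, tip: TipModel) -> np.ndarray:
    """1D contact profile of a translationally invariant surface."""
    d = np.abs(xs[:, None] - px[None, :])
    return np.maximum((pz[None, :] - tip.z(d)).max(axis=1), 0.0)


def _cylinder_profile(xs: np.ndarray, radius: float, x_c: float, tip: TipModel) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, 721, endpoint=False)
    px = x_c + radius * np.cos(t)
    pz = radius + radius * np.sin(t)
    return _dilate_profile_1d(xs, px, pz, tip)


def estimate_tip_radius(
    straight_img: HeightMap,
    half_angle_deg: float = 18.0,
    bounds_nm: Tuple[float, float] = (0.05, 100.0),
) -> float:
    """Estimate the tip apex radius from a straightened fibril image.

    Least-squares fit of a tip-sample contact model (cylinder of radius a
    resting on the substrate, imaged by a sphere-capped cone of radius R)
    to the mean transverse cross-section of the fibril, with R (and a,
    and the lateral centre) as fitted parameters.
    """
    prof = straight_img.heights.mean(axis=0)
    xs = straight_img.x0 + np.arange(prof.size) * straight_img.pixel_size_nm
    hmax = prof.max()
    if hmax <= 0:
        raise UndefinedScoreError("image has no fibril signal")
    a0 = hmax / 2.0
    x_c0 = float(xs[np.argmax(prof)])

    def resid(p):
        radius, a, x_c = p
        tip = TipModel(radius_nm=radius, half_angle_deg=half_angle_deg)
        return _cylinder_profile(xs, a, x_c, tip) - prof

    res = least_squares(
        resid,
        x0=[10.0, a0, x_c0],
        bounds=([bounds_nm[0], 0.1, xs[0]], [bounds_nm[1], 4 * a0 + 1.0, xs[-1]]),
        xtol=1e-10,
        ftol=1e-10,
    )
    radius = float(res.x[0])
    rel = 1e-3
    if not res.success or radius <= bounds_nm[0] * (1 + rel) or radius >= bounds_nm[1] * (1 - rel):
        warnings.warn(
            f"tip radius estimate {radius:.2f} nm at search bound or fit failed",
            EstimationWarning,
        )
    return radius


# --------------------------------------------------------------------------
# periodicity optimisation

def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise UndefinedScoreError("zero-variance image in cross-correlation")
    return float(a.ravel() @ b.ravel() / (na * nb))


def _resample_y(sim: np.ndarray, scale: float, ny_out: int, shift: float = 0.0) -> np.ndarray:
    """Stretch sim along y by ``scale`` about its centre and shift, sampled
    on ny_out rows."""
    ny_s, nx = sim.shape
    yc_s, yc_o = (ny_s - 1) / 2.0, (ny_out - 1) / 2.0
    rows = yc_s + (np.arange(ny_out) - yc_o) / scale + shift
    cols = np.arange(nx)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(sim, [rr, cc], order=1, mode="nearest")


def optimize_periodicity(
    sim: HeightMap,
    data: HeightMap,
    bounds: Tuple[float, float] = (0.5, 2.0),
    mask_threshold_nm: Optional[float] = None,
    max_shift_rows: Optional[int] = None,
) -> Tuple[float, HeightMap, float]:
    """Dilate/contract a simulated image along the fibril axis to match data.

    Searches the axial scale factor within ``bounds`` (the plausible
    structural-variation interval) for the value maximising the
    normalised cross-correlation with the experimental image over the
    fibril footprint.  Because the simulated helix starts at an
    arbitrary phase, an axial registration shift (up to one apparent
    period, or ``max_shift_rows``) is optimised jointly with the scale.
    Returns (scale, resampled image, correlation); warns if the optimal
    scale sits at a bound.
    """
    if abs(sim.pixel_size_nm - data.pixel_size_nm) > 1e-9:
        raise ValueError("sim and data must share a pixel size")
    dat = data.heights
    if np.allclose(dat, dat.flat[0]):
        raise UndefinedScoreError("flat data image: correlation undefined")
    if mask_threshold_nm is None:
        mask_threshold_nm = 0.05 * float(dat.max())
    mask = dat > mask_threshold_nm
    if mask.sum() < 10:
        raise UndefinedScoreError("fibril footprint mask nearly empty")

    ny_d = dat.shape[0]
    ny_s = sim.heights.shape[0]
    d_masked = dat[mask]

    def stretched(s: float) -> np.ndarray:
        """Whole sim stretched by s: row i samples sim at i/s."""
        n_out = int(np.floor((ny_s - 1) * s)) + 1
        rows = np.arange(n_out) / s
        cols = np.arange(sim.heights.shape[1])
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        return ndimage.map_coordinates(sim.heights, [rr, cc], order=1, mode="nearest")

    def best_shift(s: float) -> Tuple[float, int]:
        r_full = stretched(s)
        n_sh = r_full.shape[0] - ny_d
        if max_shift_rows is not None:
            n_sh = min(n_sh, max_shift_rows)
        if n_sh < 0:
            return -np.inf, 0
        best_c, best_sh = -np.inf, 0
        for sh in range(n_sh + 1):
            c = _ncc(r_full[sh : sh + ny_d][mask], d_masked)
            if c > best_c:
                best_c, best_sh = c, sh
        return best_c, best_sh

    grid = np.arange(bounds[0], bounds[1] + 1e-9, 0.02)
    results = [best_shift(float(s)) for s in grid]
    vals = np.array([r[0] for r in results])
    k = int(np.argmax(vals))
    fine = np.arange(
        max(grid[k] - 0.02, bounds[0]), min(grid[k] + 0.02, bounds[1]) + 1e-9, 0.002
    )
    fresults = [best_shift(float(s)) for s in fine]
    fvals = np.array([r[0] for r in fresults])
    kf = int(np.argmax(fvals))
    s_best = float(fine[kf])
    c_best, sh_best = fresults[kf]

    if s_best <= bounds[0] + 1e-9 or s_best >= bounds[1] - 1e-9:
        warnings.warn(
            f"periodicity scale clamped at interval bound {s_best:.3f}",
            BoundaryWarning,
        )
    out = HeightMap(
        heights=stretched(s_best)[sh_best : sh_best + ny_d],
        pixel_size_nm=sim.pixel_size_nm,
        axis_height_nm=sim.axis_height_nm,
        x0=sim.x0,
        y0=data.y0,
    )
    return s_best, out, float(c_best)


# --------------------------------------------------------------------------
# HeightMap I/O

def save_heightmap_tsv(img: HeightMap, path) -> None:
    """Plain TSV grid plus a JSON sidecar; bit-exact round trip."""
    path = Path(path)
    np.savetxt(path, img.heights, delimiter="\t", fmt="%.17g")
    sidecar = {
        "pixel_size_nm": img.pixel_size_nm,
        "axis_height_nm": img.axis_height_nm,
        "x0": img.x0,
        "y0": img.y0,
        "units": "nm",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_heightmap_tsv(path) -> HeightMap:
    path = Path(path)
    heights = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return HeightMap(
        heights=heights,
        pixel_size_nm=meta["pixel_size_nm"],
        axis_height_nm=meta.get("axis_height_nm"),
        x0=meta.get("x0", 0.0),
        y0=meta.get("y0", 0.0),
    )


def save_heightmap_tiff(img: HeightMap, path) -> None:
    import tifffile

    tifffile.imwrite(
        str(path),
        img.heights.astype(np.float32),
        metadata={"pixel_size_nm": img.pixel_size_nm},
    )


def load_heightmap_tiff(path, pixel_size_nm: float) -> HeightMap:
    import tifffile

    return HeightMap(heights=tifffile.imread(str(path)), pixel_size_nm=pixel_size_nm)
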
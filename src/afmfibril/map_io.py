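"""Cryo-EM density map input and iso-surface handling.

Reads MRC/CCP4 volumes (via :mod:`gemmi`), extracts marching-cubes
iso-surfaces, denoises vertex clouds and aligns the fibril long axis with
the z-axis.  All coordinates inside the package are nanometres; MRC headers
carry Angstroms and are converted on read.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import gemmi
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from skimage import measure

from .errors import (
    AmbiguousAxisError,
    EmptySurfaceError,
    FormatError,
    UnsupportedGridError,
)

ANGSTROM_PER_NM = 10.0


@dataclass
class HelicalParams:
    """Helical symmetry of a filament.

    twist_deg is the signed rotation per subunit about the screw axis
    (internal convention: left-handed filaments have twist_deg < 0),
    rise_nm the translation per subunit, and symmetry_order the C_n
    rotational symmetry of the cross-section.
    """

    twist_deg: float
    rise_nm: float
    handedness: int
    symmetry_order: int = 1

    def __post_init__(self) -> None:
        if self.rise_nm <= 0:
            raise ValueError(f"rise_nm must be > 0, got {self.rise_nm}")
        if self.handedness not in (-1, 1):
            raise ValueError(f"handedness must be -1 or +1, got {self.handedness}")
        if self.symmetry_order < 1:
            raise ValueError("symmetry_order must be >= 1")
        if self.twist_deg != 0 and int(np.sign(self.twist_deg)) != self.handedness:
            raise ValueError(
                "sign of twist_deg must match handedness "
                f"(twist {self.twist_deg}, handedness {self.handedness})"
            )

    @property
    def omega_rad_per_nm(self) -> float:
        """Rotation rate about the axis, radians per nm of axial travel."""
        return np.deg2rad(self.twist_deg) / self.rise_nm

    @property
    def pitch_nm(self) -> float:
        """Axial distance for a full 360 deg rotation."""
        if self.twist_deg == 0:
            return np.inf
        return 360.0 / abs(self.twist_deg) * self.rise_nm

    @property
    def crossover_nm(self) -> float:
        """Apparent cross-over distance: the cross-section pattern repeats
        every 2*pi/n of rotation, i.e. pitch / symmetry_order."""
        return self.pitch_nm / self.symmetry_order

    @classmethod
    def from_metadata(
        cls,
        twist_deg: float,
        rise_nm: float,
        handedness: Optional[int] = None,
        symmetry_order: int = 1,
        rise_unit: str = "nm",
    ) -> "HelicalParams":
        """Build from EMDB-style metadata, normalising sign conventions.

        If handedness is given it wins and the twist sign is adjusted to
        match; otherwise handedness is inferred from the twist sign.
        rise may be declared in Angstroms with ``rise_unit='A'``.
        """
        if rise_unit in ("A", "angstrom", "Å"):
            rise_nm = rise_nm / ANGSTROM_PER_NM
        elif rise_unit != "nm":
            raise ValueError(f"unknown rise_unit {rise_unit!r}")
        if handedness is None:
            handedness = -1 if twist_deg < 0 else 1
        twist_deg = handedness * abs(twist_deg)
        return cls(twist_deg, rise_nm, int(handedness), symmetry_order)


@dataclass
class VolumeGrid:
    """Voxelised density map.

    data is indexed [ix, iy, iz]; physical position of voxel centre
    (i, j, k) is origin + voxel_size * (i, j, k), in nm.
    """

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    isovalue: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 2:
            raise FormatError(f"volume must be 3D with all dims >= 2, shape {self.data.shape}")
        if not self.voxel_size > 0:
            raise FormatError(f"voxel_size must be > 0, got {self.voxel_size}")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("density values must be finite")


@dataclass
class SurfaceCloud:
    """3D vertex set of an iso-surface or phantom surface (nm)."""

    vertices: np.ndarray
    faces: Optional[np.ndarray] = None
    helical: Optional[HelicalParams] = None
    voxel_size: Optional[float] = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (N, 3) array")
        if self.vertices.shape[0] < 4:
            raise EmptySurfaceError("surface needs at least 4 vertices")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("vertex coordinates must be finite")
        if self.faces is not None:
            self.faces = np.asarray(self.faces, dtype=np.int64)
            if self.faces.size and self.faces.max() >= len(self.vertices):
                raise ValueError("face indices out of range")

    def replace(self, **kw) -> "SurfaceCloud":
        return dataclasses.replace(self, **kw)

    @property
    def z_extent(self) -> float:
        z = self.vertices[:, 2]
        return float(z.max() - z.min())


@dataclass
class RigidTransform:
    """v' = rotation @ (v - pivot) + translation."""

    rotation: np.ndarray
    pivot: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.pivot) @ self.rotation.T + self.translation


def read_volume(path, isovalue: Optional[float] = None) -> VolumeGrid:
    """Read an MRC/CCP4 map, converting header Angstroms to nm.

    Voxels must be isotropic within 1%; the map origin (header origin
    words, falling back to the start indices) is honoured.
    """
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot read MRC/CCP4 map {path}: {exc}") from exc
    data = np.array(m.grid, copy=True)
    if data.ndim != 3 or min(data.shape) < 1:
        raise FormatError(f"map {path} has degenerate dimensions {data.shape}")
    spacing = np.array(m.grid.spacing, dtype=float)  # Angstrom
    if np.any(spacing <= 0):
        raise FormatError(f"map {path} has non-positive voxel spacing {spacing}")
    if spacing.max() / spacing.min() - 1.0 > 0.01:
        raise UnsupportedGridError(
            f"anisotropic voxels beyond 1% tolerance: {spacing} A"
        )
    voxel_nm = float(spacing.mean()) / ANGSTROM_PER_NM
    origin_words = np.array(
        [m.header_float(50), m.header_float(51), m.header_float(52)], dtype=float
    )
    if np.any(origin_words != 0):
        origin_nm = origin_words / ANGSTROM_PER_NM
    else:
        nstart = np.array(
            [m.header_i32(5), m.header_i32(6), m.header_i32(7)], dtype=float
        )
        origin_nm = nstart * spacing / ANGSTROM_PER_NM
    return VolumeGrid(data=data, voxel_size=voxel_nm, origin=origin_nm, isovalue=isovalue)


def write_volume(volume: VolumeGrid, path) -> None:
    """Write a VolumeGrid as an MRC/CCP4 map (nm converted back to A)."""
    m = gemmi.Ccp4Map()
    grid = gemmi.FloatGrid(np.ascontiguousarray(volume.data, dtype=np.float32))
    a = volume.data.shape[0] * volume.voxel_size * ANGSTROM_PER_NM
    b = volume.data.shape[1] * volume.voxel_size * ANGSTROM_PER_NM
    c = volume.data.shape[2] * volume.voxel_size * ANGSTROM_PER_NM
    grid.set_unit_cell(gemmi.UnitCell(a, b, c, 90.0, 90.0, 90.0))
    m.grid = grid
    m.update_ccp4_header()
    origin_a = np.asarray(volume.origin, dtype=float) * ANGSTROM_PER_NM
    for i, w in enumerate(origin_a):
        m.set_header_float(50 + i, float(w))
    m.write_ccp4_map(str(path))


def extract_isosurface(volume: VolumeGrid, isovalue: Optional[float] = None) -> SurfaceCloud:
    """Marching-cubes iso-surface of a density map, vertices in nm."""
    if isovalue is None:
        isovalue = volume.isovalue
    if isovalue is None:
        raise ValueError("no isovalue given and none stored on the volume")
    lo, hi = float(volume.data.min()), float(volume.data.max())
    if not lo < isovalue < hi:
        raise ValueError(f"isovalue {isovalue} outside data range [{lo}, {hi}]")
    verts, faces, _, _ = measure.marching_cubes(
        volume.data, level=isovalue, spacing=(volume.voxel_size,) * 3
    )
    verts = verts + volume.origin
    return SurfaceCloud(vertices=verts, faces=faces, voxel_size=volume.voxel_size)


def denoise_surface(
    surface: SurfaceCloud,
    k_neighbors: int = 8,
    dist_factor: float = 3.0,
    alpha_radius: Optional[float] = None,
) -> SurfaceCloud:
    """Remove outlier vertices and keep the largest connected surface region.

    Vertices whose mean distance to their k nearest neighbours exceeds
    ``dist_factor`` times the median of that statistic are dropped; the
    survivors are then clustered with a single-linkage cutoff of
    2 * alpha_radius (two points can share an alpha-ball only if closer
    than that) and only the largest cluster is retained.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if alpha_radius is None:
        if surface.voxel_size is None:
            raise ValueError("alpha_radius not given and surface has no voxel_size")
        alpha_radius = 2.0 * surface.voxel_size
    if alpha_radius <= 0:
        raise ValueError("alpha_radius must be > 0")

    verts = surface.vertices
    tree = cKDTree(verts)
    # k+1 because each vertex is its own nearest neighbour
    dists, _ = tree.query(verts, k=k_neighbors + 1)
    mean_knn = dists[:, 1:].mean(axis=1)
    keep = mean_knn <= dist_factor * np.median(mean_knn)
    if not keep.any():
        raise EmptySurfaceError("k-NN filtering removed every vertex")

    kept_idx = np.flatnonzero(keep)
    sub = verts[kept_idx]
    subtree = cKDTree(sub)
    pairs = subtree.query_pairs(r=2.0 * alpha_radius, output_type="ndarray")
    n = len(sub)
    if len(pairs):
        g = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        ncomp, labels = connected_components(g, directed=False)
    else:
        ncomp, labels = n, np.arange(n)
    largest = np.argmax(np.bincount(labels))
    final_idx = kept_idx[labels == largest]
    if len(final_idx) < 4:
        raise EmptySurfaceError("largest region has fewer than 4 vertices")

    faces = None
    if surface.faces is not None:
        remap = -np.ones(len(verts), dtype=np.int64)
        remap[final_idx] = np.arange(len(final_idx))
        f = remap[surface.faces]
        faces = f[(f >= 0).all(axis=1)]
    return surface.replace(vertices=verts[final_idx], faces=faces)


def _principal_axes(verts: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    centroid = verts.mean(axis=0)
    centred = verts - centroid
    _, svals, vt = np.linalg.svd(centred, full_matrices=False)
    return centroid, svals, vt


def align_long_axis(surface: SurfaceCloud) -> Tuple[SurfaceCloud, RigidTransform]:
    """Rotate/translate a surface so its long principal axis runs along +z.

    The centroid moves to the origin.  The residual z-flip ambiguity is
    resolved deterministically by making the third central moment
    (skewness) of the z-coordinates non-negative.
    """
    centroid, svals, vt = _principal_axes(surface.vertices)
    if svals[0] < 2.0 * svals[1]:
        raise AmbiguousAxisError(
            f"point cloud too isotropic for axis alignment (sv ratio "
            f"{svals[0] / svals[1]:.2f} < 2)"
        )
    # rows of vt: principal directions, longest first -> map to (z, x, y)
    rot = np.vstack([vt[1], vt[2], vt[0]])
    if np.linalg.det(rot) < 0:
        rot[1] = -rot[1]
    new = (surface.vertices - centroid) @ rot.T
    z = new[:, 2]
    if np.mean((z - z.mean()) ** 3) < 0:
        flip = np.diag([1.0, -1.0, -1.0])  # rotate pi about x: keeps det +1
        rot = flip @ rot
        new = new @ flip.T
    tf = RigidTransform(rotation=rot, pivot=centroid, translation=np.zeros(3))
    return surface.replace(vertices=new), tf


def export_surface(surface: SurfaceCloud, path) -> None:
    """Export as PLY/OBJ (by extension) for inspection in external viewers."""
    import trimesh

    if surface.faces is not None and len(surface.faces):
        mesh = trimesh.Trimesh(
            vertices=surface.vertices, faces=surface.faces, process=False
        )
        mesh.export(str(path))
    else:
        trimesh.PointCloud(surface.vertices).export(str(path))
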
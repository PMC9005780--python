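"""Synthetic helical fibril phantoms with known ground truth.

Phantoms stand in for deposited cryo-EM maps and experimental AFM
images: a parametric closed cross-section is swept helically into a
surface cloud and (optionally) voxelised into a density map, and noisy
topographs are simulated with the same contact model used for real
comparisons.  Every ground-truth quantity a phantom records (symmetry,
handedness, cross-over, cross-sectional area, axis height) is meant to
be recoverable by the analysis pipeline within its stated tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import GeometryError
from .map_io import HelicalParams, SurfaceCloud, VolumeGrid
from .tipsim import HeightMap, TipModel, simulate_topograph, to_image_frame


@dataclass
class CrossSectionSpec:
    """Star-shaped parametric cross-section r(theta).

    kind='ellipse': semi-axes a, b (C2 symmetric).
    kind='fourier': r(theta) = r0 * (1 + sum_k amp * cos(k theta + phase))
    with harmonic orders restricted to multiples of the symmetry order.
    """

    kind: str
    a: float = 4.0
    b: float = 2.0
    r0: float = 3.0
    harmonics: Dict[int, Tuple[float, float]] = field(default_factory=dict)

    def symmetry_order(self) -> int:
        if self.kind == "ellipse":
            return 2
        orders = [k for k in self.harmonics if self.harmonics[k][0] != 0]
        if not orders:
            return 1  # circle: report C1 (every n fits; convention)
        g = orders[0]
        for k in orders[1:]:
            g = np.gcd(g, k)
        return int(g)

    def radius(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if self.kind == "ellipse":
            a, b = self.a, self.b
            return a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        if self.kind == "fourier":
            r = np.ones_like(theta)
            for k, (amp, phase) in self.harmonics.items():
                r = r + amp * np.cos(k * theta + phase)
            if np.any(r <= 0):
                raise GeometryError("fourier cross-section radius not positive")
            return self.r0 * r
        raise ValueError(f"unknown cross-section kind {self.kind!r}")

    def points(self, n_pts: int = 360) -> np.ndarray:
        t = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
        r = self.radius(t)
        return np.column_stack([r * np.cos(t), r * np.sin(t)])

    def area(self, n_pts: int = 2048) -> float:
        """Enclosed area by dense shoelace evaluation of the spec curve."""
        p = self.points(n_pts)
        x, y = p[:, 0], p[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    def r_max(self, n_pts: int = 2048) -> float:
        t = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
        return float(self.radius(t).max())


@dataclass
class PhantomTruth:
    """Ground-truth record for one phantom."""

    label: str
    symmetry_order: int
    handedness: int
    twist_deg: float
    rise_nm: float
    cod_nm: float
    csa_nm2: float
    axis_height_nm: float
    voxel_nm: float


@dataclass
class Phantom:
    label: str
    surface: SurfaceCloud
    truth: PhantomTruth
    spec: CrossSectionSpec
    volume: Optional[VolumeGrid] = None


def make_phantom(
    spec: CrossSectionSpec,
    twist_deg: float,
    rise_nm: float,
    length_nm: float,
    voxel_nm: float = 0.5,
    label: str = "phantom",
    with_volume: bool = False,
) -> Phantom:
    """Sweep a cross-section helically into a surface (and optional map).

    The section at height z is the base curve rotated by
    omega * z (omega = twist/rise); the screw axis is the z-axis.  The
    optional density map is a binary solid softened by a 1-voxel
    Gaussian, so the 0.5 iso-surface reproduces the phantom boundary.
    Truth records cod = pitch / n (the pattern repeats after 2*pi/n of
    rotation) and the axis height r_max of a filament resting on a flat
    substrate.
    """
    handedness = -1 if twist_deg < 0 else 1
    helical = HelicalParams(
        twist_deg=twist_deg,
        rise_nm=rise_nm,
        handedness=handedness,
        symmetry_order=spec.symmetry_order(),
    )
    omega = helical.omega_rad_per_nm
    n = helical.symmetry_order

    r_max = spec.r_max()
    arc_step = voxel_nm / 2.0
    n_ring = max(36, int(np.ceil(2 * np.pi * r_max / arc_step)))
    t = np.linspace(0, 2 * np.pi, n_ring, endpoint=False)
    base_r = spec.radius(t)
    zs = np.arange(0.0, length_nm + voxel_nm / 4, voxel_nm / 2.0)
    pts = np.empty((len(zs) * n_ring, 3))
    for i, z in enumerate(zs):
        ang = t + omega * z
        sl = slice(i * n_ring, (i + 1) * n_ring)
        pts[sl, 0] = base_r * np.cos(ang)
        pts[sl, 1] = base_r * np.sin(ang)
        pts[sl, 2] = z
    surface = SurfaceCloud(vertices=pts, voxel_size=voxel_nm, helical=helical)

    truth = PhantomTruth(
        label=label,
        symmetry_order=n,
        handedness=handedness,
        twist_deg=twist_deg,
        rise_nm=rise_nm,
        cod_nm=helical.crossover_nm,
        csa_nm2=spec.area(),
        axis_height_nm=r_max,
        voxel_nm=voxel_nm,
    )

    volume = None
    if with_volume:
        margin = 3 * voxel_nm
        half = r_max + margin
        nxy = int(np.ceil(2 * half / voxel_nm)) + 1
        nz = int(np.ceil(length_nm / voxel_nm)) + 1
        xs = -half + np.arange(nxy) * voxel_nm
        gx, gy = np.meshgrid(xs, xs, indexing="ij")
        g_r = np.hypot(gx, gy)
        g_t = np.arctan2(gy, gx)
        data = np.zeros((nxy, nxy, nz))
        for k in range(nz):
            z = k * voxel_nm
            # star-shaped inside test: r_pixel <= r_curve(theta - omega z)
            data[:, :, k] = (g_r <= spec.radius(g_t - omega * z)).astype(float)
        data = gaussian_filter(data, sigma=1.0)
        volume = VolumeGrid(
            data=data,
            voxel_size=voxel_nm,
            origin=np.array([-half, -half, 0.0]),
            isovalue=0.5,
        )
    return Phantom(label=label, surface=surface, truth=truth, spec=spec, volume=volume)


def simulate_noisy_afm(
    surface: SurfaceCloud,
    tip: TipModel,
    pixel_nm: float,
    noise_sd_nm: float = 0.0,
    seed: int = 0,
    line_noise_sd_nm: float = 0.0,
) -> HeightMap:
    """Simulated topograph with additive Gaussian pixel noise and
    optional per-scan-line height offsets.

    The surface is taken in the axis-aligned frame (axis = z) and is
    rotated into the imaging frame internally.  Identical seeds give
    identical images.
    """
    if noise_sd_nm < 0 or line_noise_sd_nm < 0:
        raise ValueError("noise levels must be >= 0")
    img = simulate_topograph(to_image_frame(surface), tip, pixel_nm, densify=False)
    if noise_sd_nm == 0 and line_noise_sd_nm == 0:
        return img
    rng = np.random.default_rng(seed)
    h = img.heights + rng.normal(0.0, noise_sd_nm, img.heights.shape)
    if line_noise_sd_nm > 0:
        h = h + rng.normal(0.0, line_noise_sd_nm, (h.shape[0], 1))
    return HeightMap(heights=h, pixel_size_nm=pixel_nm, x0=img.x0, y0=img.y0)


def decoy_panel(
    n_decoys: int,
    seed: int = 0,
    rise_nm: float = 0.47,
    length_nm: float = 30.0,
    voxel_nm: float = 0.5,
    with_volume: bool = False,
) -> List[Phantom]:
    """Deterministic panel of structurally diverse phantoms.

    Alternates C1 and C2 cross-sections (at least one of each), spans at
    least a 2x range of cross-sectional areas and a range of twists, and
    mixes handedness.  The same seed reproduces identical truth records.
    """
    if n_decoys < 2:
        raise ValueError("n_decoys must be >= 2")
    rng = np.random.default_rng(seed)
    # stratify size and cross-over across the panel so no two decoys are
    # near-duplicates: sizes span >= 2x area range, cods cover the
    # 35-75 nm window typical of tau fibrils
    sizes = np.linspace(2.2, 4.5, n_decoys) + rng.uniform(-0.1, 0.1, n_decoys)
    cods = rng.permutation(np.linspace(35.0, 75.0, n_decoys))
    phantoms = []
    for i in range(n_decoys):
        size = float(sizes[i])
        if i % 2 == 0:
            n_sym = 2
            spec = CrossSectionSpec(
                kind="ellipse", a=size, b=size * rng.uniform(0.45, 0.65)
            )
        else:
            n_sym = 1
            spec = CrossSectionSpec(
                kind="fourier",
                r0=size * 0.8,
                harmonics={
                    1: (0.28 + 0.1 * rng.random(), float(rng.uniform(0, 2 * np.pi))),
                    2: (0.12, float(rng.uniform(0, 2 * np.pi))),
                },
            )
        cod = float(cods[i])
        twist = -360.0 / (n_sym * cod) * rise_nm
        if i % 5 == 4:
            twist = -twist  # occasional right-handed decoy
        phantoms.append(
            make_phantom(
                spec,
                twist_deg=float(twist),
                rise_nm=rise_nm,
                length_nm=length_nm,
                voxel_nm=voxel_nm,
                label=f"decoy{i:02d}",
                with_volume=with_volume,
            )
        )
    return phantoms
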
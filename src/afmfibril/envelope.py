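"""3D surface-envelope reconstruction of a fibril from its AFM topograph.

The straightened topograph is first tip-deconvolved (grey-scale erosion
by the reflected tip), recovering the contact-point surface.  Because a
helical filament rotates its cross-section by 2*pi/n per cross-over
distance along the axis, every axial slice views the same cross-section
at a different phase: accumulating the deconvolved upper-surface points
into rotationally mapped angular bins yields the full radial function
r(theta) about the screw axis, with per-bin dispersion retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import AmbiguousSymmetryWarning, CoverageError, UndefinedScoreError
from .map_io import SurfaceCloud
from .sections import CrossSection
from .tipsim import HeightMap, TipModel, erode_topograph, simulate_topograph


@dataclass
class Envelope3D:
    """Reconstructed fibril envelope as a radial function about the screw axis.

    ``r_mean`` holds the mean radius per angular bin over one symmetric
    sector [0, 2*pi/n); ``samples`` the per-bin radius samples pooled
    across axial positions (for percentile bounds).  ``axis_height_nm``
    is the elevation of the screw axis above the substrate, equal to the
    maximum radius for a rigid filament resting on a flat support.
    """

    r_mean: np.ndarray
    theta: np.ndarray
    samples: List[np.ndarray]
    symmetry_order: int
    cod_nm: float
    handedness: int
    axis_height_nm: float
    phase0_rad: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.r_mean <= 0):
            raise ValueError("envelope radii must be positive")
        if self.axis_height_nm <= 0:
            raise ValueError("axis height must be positive")

    @property
    def omega_rad_per_nm(self) -> float:
        """Signed rotation rate of the cross-section along the axis."""
        return self.handedness * 2.0 * np.pi / (self.symmetry_order * self.cod_nm)

    def r_full(self) -> Tuple[np.ndarray, np.ndarray]:
        """Radius over the full turn, replicated n-fold."""
        n = self.symmetry_order
        sector = 2.0 * np.pi / n
        thetas = np.concatenate([self.theta + k * sector for k in range(n)])
        return thetas, np.tile(self.r_mean, n)

    def surface_points(
        self, length_nm: float, dz_nm: float, arc_step_nm: Optional[float] = None
    ) -> SurfaceCloud:
        """Sample the helical surface in the axis-aligned frame (axis = z).

        The base cross-section at z = 0 is swept along z with the
        envelope's rotation rate; point spacing is dz_nm axially and
        about arc_step_nm (default dz_nm) around the section.
        """
        thetas, radii = self.r_full()
        if arc_step_nm is None:
            arc_step_nm = dz_nm
        # upsample the ring so arc spacing <= arc_step_nm
        mean_r = float(radii.mean())
        n_ring = max(len(thetas), int(np.ceil(2 * np.pi * mean_r / arc_step_nm)))
        t_dense = np.linspace(0, 2 * np.pi, n_ring, endpoint=False)
        r_dense = np.interp(t_dense, thetas, radii, period=2 * np.pi)
        zs = np.arange(0.0, length_nm + dz_nm / 2, dz_nm)
        omega = self.omega_rad_per_nm
        pts = np.empty((len(zs) * n_ring, 3))
        for i, z in enumerate(zs):
            ang = t_dense + self.phase0_rad + omega * z
            pts[i * n_ring : (i + 1) * n_ring, 0] = r_dense * np.cos(ang)
            pts[i * n_ring : (i + 1) * n_ring, 1] = r_dense * np.sin(ang)
            pts[i * n_ring : (i + 1) * n_ring, 2] = z
        return SurfaceCloud(vertices=pts)

    def export(self, path_prefix) -> None:
        """Write the envelope as JSON (r-grid) plus a PLY mesh."""
        import json
        from pathlib import Path

        prefix = Path(path_prefix)
        prefix.with_suffix(".json").write_text(
            json.dumps(
                {
                    "theta_rad": self.theta.tolist(),
                    "r_mean_nm": self.r_mean.tolist(),
                    "symmetry_order": self.symmetry_order,
                    "cod_nm": self.cod_nm,
                    "handedness": self.handedness,
                    "axis_height_nm": self.axis_height_nm,
                }
            )
        )
        from .map_io import export_surface

        cloud = self.surface_points(length_nm=2 * self.cod_nm, dz_nm=0.5)
        export_surface(cloud, prefix.with_suffix(".ply"))


def _denoise_for_deconvolution(img: HeightMap) -> HeightMap:
    """Noise-adaptive pre-smoothing before grey-scale erosion.

    Erosion is a windowed minimum, so uncorrelated pixel noise biases the
    deconvolved surface downward by a couple of noise SDs.  The substrate
    noise level is estimated robustly (MAD of pixels below 10% of the
    peak); when it is non-negligible the image is smoothed with a 1-pixel
    Gaussian, which leaves noise-free simulations untouched.
    """
    h = img.heights
    low = h[h < 0.1 * h.max()]
    if low.size < 20:
        return img
    sd = 1.4826 * float(np.median(np.abs(low - np.median(low))))
    if sd <= 0.02 * h.max():
        return img
    from scipy.ndimage import gaussian_filter

    return HeightMap(
        heights=gaussian_filter(h, sigma=1.0),
        pixel_size_nm=img.pixel_size_nm,
        axis_height_nm=img.axis_height_nm,
        x0=img.x0,
        y0=img.y0,
    )


def _estimate_axis(eroded: np.ndarray, pixel: float, x0: float) -> Tuple[float, float]:
    """Estimate axis lateral position (nm) and elevation (nm) from the
    deconvolved image: footprint-weighted centroid, and half the robust
    peak of the per-row maxima (a resting filament's highest point is
    twice the axis height)."""
    h = eroded
    w = np.clip(h, 0.0, None)
    xs = x0 + np.arange(h.shape[1]) * pixel
    x_axis = float((w * xs[None, :]).sum() / w.sum())
    row_max = h.max(axis=1)
    a = float(np.percentile(row_max, 98)) / 2.0
    return x_axis, a


def reconstruct_envelope(
    straight_img: HeightMap,
    tip: TipModel,
    symmetry_order: int,
    cod_nm: float,
    handedness: int,
    axis_height_nm: Optional[float] = None,
    axis_x_nm: Optional[float] = None,
    n_theta_bins: Optional[int] = None,
    max_empty_frac: float = 0.10,
) -> Envelope3D:
    """Reconstruct the 3D envelope of a straightened fibril topograph.

    Steps: (i) tip-deconvolve the image by grey-scale erosion with the
    same tip model used for simulation; (ii) treat each axial position y
    as a view of the cross-section rotated by handedness * 2*pi *
    y / (n * cod); (iii) map deconvolved surface pixels above the axis
    plane into (theta, r) polar bins of the common cross-section frame;
    (iv) average per bin, keeping the sample dispersion.

    Raises :class:`CoverageError` if the image is shorter than one
    cross-over or more than ``max_empty_frac`` of the bins stay empty.
    """
    if symmetry_order < 1:
        raise ValueError("symmetry_order must be >= 1")
    if handedness not in (-1, 1):
        raise ValueError("handedness must be -1 or +1")
    px = straight_img.pixel_size_nm
    ny, nx = straight_img.shape
    if (ny - 1) * px < cod_nm:
        raise CoverageError(
            f"image length {(ny - 1) * px:.1f} nm shorter than one cross-over "
            f"({cod_nm:.1f} nm)"
        )
    eroded = erode_topograph(_denoise_for_deconvolution(straight_img), tip)
    x_est, a_est = _estimate_axis(eroded.heights, px, straight_img.x0)
    x_axis = x_est if axis_x_nm is None else axis_x_nm
    a = a_est if axis_height_nm is None else axis_height_nm

    n = symmetry_order
    sector = 2.0 * np.pi / n
    omega = handedness * 2.0 * np.pi / (n * cod_nm)

    xs = straight_img.x0 + np.arange(nx) * px
    ys = np.arange(ny) * px
    gx, gy = np.meshgrid(xs, ys)
    accept = eroded.heights > a * 1.02
    dx = gx[accept] - x_axis
    dz = eroded.heights[accept] - a
    r_all = np.hypot(dx, dz)
    theta_base = np.arctan2(dz, dx) + omega * gy[accept]
    fold = np.mod(theta_base, sector)

    if n_theta_bins is not None:
        n_bins = n_theta_bins
    else:
        # 1-deg bins when sampling allows, coarsened so bins average
        # >= ~8 samples on sparsely sampled (coarse-pixel) images
        n_bins = int(np.clip(len(r_all) // 8, 36, 360 // n))
    idx = np.floor(fold / sector * n_bins).astype(int) % n_bins
    bin_samples: List[List[float]] = [[] for _ in range(n_bins)]
    for b, rv in zip(idx, r_all):
        bin_samples[b].append(float(rv))

    counts = np.array([len(s) for s in bin_samples])
    empty = counts == 0
    if empty.mean() > max_empty_frac:
        raise CoverageError(
            f"{empty.sum()}/{n_bins} angular bins empty "
            f"({100 * empty.mean():.0f}% > {100 * max_empty_frac:.0f}%)"
        )
    theta = (np.arange(n_bins) + 0.5) / n_bins * sector
    r_mean = np.array([np.mean(s) if s else np.nan for s in bin_samples])
    if empty.any():  # fill rare gaps by periodic interpolation
        good = ~empty
        r_mean[empty] = np.interp(
            theta[empty], theta[good], r_mean[good], period=sector
        )
    samples = [np.asarray(s) if s else np.array([r_mean[k]]) for k, s in enumerate(bin_samples)]
    return Envelope3D(
        r_mean=r_mean,
        theta=theta,
        samples=samples,
        symmetry_order=n,
        cod_nm=cod_nm,
        handedness=handedness,
        axis_height_nm=float(np.max(r_mean)),
        phase0_rad=0.0,
    )


def envelope_cross_section(env: Envelope3D, percentiles: Tuple[float, float] = (2.5, 97.5)) -> CrossSection:
    """Mean cross-section of the envelope with percentile bounds.

    The mean radial curve is replicated n-fold over the full turn; the
    lower/upper curves are the per-bin 2.5 and 97.5 percentiles of the
    pooled axial samples.  The screw axis sits at the origin.
    """
    thetas, r = env.r_full()
    lo = np.concatenate(
        [np.array([np.percentile(s, percentiles[0]) for s in env.samples])]
        * env.symmetry_order
    )
    hi = np.concatenate(
        [np.array([np.percentile(s, percentiles[1]) for s in env.samples])]
        * env.symmetry_order
    )
    unit = np.column_stack([np.cos(thetas), np.sin(thetas)])
    return CrossSection(
        points=unit * r[:, None],
        lower=unit * lo[:, None],
        upper=unit * hi[:, None],
        axis_xy=np.zeros(2),
    )


def resimulate(
    env: Envelope3D,
    template: HeightMap,
    tip: TipModel,
    axis_x_nm: float,
) -> HeightMap:
    """Simulate the topograph of a reconstructed envelope on the template grid.

    The surface is generated directly in the imaging frame with the same
    row-phase convention used by :func:`reconstruct_envelope` (the
    cross-section seen at image row y is the base section rotated by
    -omega * y), so the re-simulated twisting pattern is registered
    row-for-row with the input image.
    """
    px = template.pixel_size_nm
    length = (template.shape[0] - 1) * px
    thetas, radii = env.r_full()
    mean_r = float(radii.mean())
    n_ring = max(len(thetas), int(np.ceil(2 * np.pi * mean_r / (px / 2))))
    t_dense = np.linspace(0, 2 * np.pi, n_ring, endpoint=False)
    r_dense = np.interp(t_dense, thetas, radii, period=2 * np.pi)
    ys = np.arange(0.0, length + px / 4, px / 2)
    omega = env.omega_rad_per_nm
    a_rest = float(radii.max())
    pts = np.empty((len(ys) * n_ring, 3))
    for i, y in enumerate(ys):
        ang = t_dense + env.phase0_rad - omega * y
        sl = slice(i * n_ring, (i + 1) * n_ring)
        pts[sl, 0] = axis_x_nm + r_dense * np.cos(ang)
        pts[sl, 1] = template.y0 + y
        pts[sl, 2] = a_rest + r_dense * np.sin(ang)
    pts[:, 2] = np.maximum(pts[:, 2], 0.0)
    cloud = SurfaceCloud(vertices=pts)
    return simulate_topograph(
        cloud,
        tip,
        px,
        grid_shape=template.shape,
        grid_origin=(template.x0, template.y0),
        densify=False,
    )


def _fourier_mag_corr(a: np.ndarray, b: np.ndarray) -> float:
    fa = np.abs(np.fft.rfft2(a - a.mean()))
    fb = np.abs(np.fft.rfft2(b - b.mean()))
    fa, fb = fa.ravel(), fb.ravel()
    fa -= fa.mean()
    fb -= fb.mean()
    denom = np.linalg.norm(fa) * np.linalg.norm(fb)
    if denom == 0:
        raise UndefinedScoreError("zero-variance Fourier magnitude")
    return float(fa @ fb / denom)


def _masked_ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    x, y = a[mask], b[mask]
    x = x - x.mean()
    y = y - y.mean()
    denom = np.linalg.norm(x) * np.linalg.norm(y)
    if denom == 0:
        raise UndefinedScoreError("zero variance under mask")
    return float(x @ y / denom)


def detect_symmetry(
    straight_img: HeightMap,
    tip: TipModel,
    cod_nm: float,
    candidates: Sequence[int] = (1, 2),
    handedness: int = -1,
    ambiguity_margin: float = 0.01,
) -> Tuple[int, Dict[int, float], bool]:
    """Identify the helical symmetry order of an imaged fibril.

    For each candidate C_n, an envelope is reconstructed under that
    symmetry, its topograph re-simulated and compared with the input in
    direct space (normalised cross-correlation over the fibril
    footprint) and in Fourier space (correlation of 2D magnitude
    spectra); the scores are averaged.  The twisting-pattern angle on
    the surface depends on n, so the wrong symmetry smears the
    reconstruction and re-simulates poorly.

    Returns (best n, per-candidate scores, ambiguous flag); warns when
    the top two scores lie within ``ambiguity_margin`` of each other.
    """
    if not set(candidates) <= {1, 2, 3, 4}:
        raise ValueError("candidates must be a subset of {1, 2, 3, 4}")
    px = straight_img.pixel_size_nm
    eroded = erode_topograph(_denoise_for_deconvolution(straight_img), tip)
    x_axis, _ = _estimate_axis(eroded.heights, px, straight_img.x0)
    mask = straight_img.heights > 0.05 * straight_img.heights.max()
    # the axially invariant height profile is identical for every
    # candidate; the symmetry signal lives in the twist modulation, so
    # correlate after removing each column's mean along the fibril axis
    def detrend(h: np.ndarray) -> np.ndarray:
        return h - h.mean(axis=0, keepdims=True)

    data_mod = detrend(straight_img.heights)
    scores: Dict[int, float] = {}
    for n in candidates:
        try:
            env = reconstruct_envelope(
                straight_img, tip, n, cod_nm, handedness, axis_x_nm=x_axis
            )
            sim = resimulate(env, straight_img, tip, x_axis)
            sim_mod = detrend(sim.heights)
            direct = _masked_ncc(data_mod, sim_mod, mask)
            fourier = _fourier_mag_corr(
                np.where(mask, data_mod, 0.0),
                np.where(mask, sim_mod, 0.0),
            )
            scores[n] = 0.5 * direct + 0.5 * fourier
        except (CoverageError, UndefinedScoreError):
            scores[n] = -np.inf
    ordered = sorted(scores, key=lambda k: scores[k], reverse=True)
    best = ordered[0]
    ambiguous = False
    if len(ordered) > 1 and np.isfinite(scores[ordered[1]]):
        if scores[best] - scores[ordered[1]] < ambiguity_margin * max(abs(scores[best]), 1e-12):
            ambiguous = True
            warnings.warn(
                f"top symmetry candidates C{best} and C{ordered[1]} score within "
                f"{100 * ambiguity_margin:.0f}%", AmbiguousSymmetryWarning,
            )
    return best, scores, ambiguous
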
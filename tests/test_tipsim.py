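"""Tip model, contact-imaging simulation and its inverse operations."""

import warnings

import numpy as np
import pytest

from afmfibril.errors import BoundaryWarning, UndefinedScoreError
from afmfibril.map_io import SurfaceCloud
from afmfibril.tipsim import (
    HeightMap,
    TipModel,
    _resample_y,
    build_tip,
    erode_topograph,
    estimate_tip_radius,
    load_heightmap_tiff,
    load_heightmap_tsv,
    optimize_periodicity,
    save_heightmap_tiff,
    save_heightmap_tsv,
    simulate_topograph,
)

from conftest import cylinder_surface


def brute_force_topograph(pts, tip, pixel, shape, origin):
    """Independent oracle: per-pixel scan over every surface point."""
    ny, nx = shape
    x0, y0 = origin
    out = np.zeros((ny, nx))
    for i in range(ny):
        for j in range(nx):
            d = np.hypot(x0 + j * pixel - pts[:, 0], y0 + i * pixel - pts[:, 1])
            out[i, j] = max(float(np.max(pts[:, 2] - tip.z(d))), 0.0)
    return out


class TestTipModel:
    def test_apex_at_zero(self):
        for radius, angle in [(2.0, 10.0), (11.7, 18.0), (40.0, 35.0)]:
            assert build_tip(radius, angle).z(0.0) == 0.0

    def test_spherical_cap_height(self):
        # circle geometry: z = R - sqrt(R^2 - d^2); R=10, d=6 -> 2.0
        tip = build_tip(10.0, 18.0)
        assert tip.z(6.0) == pytest.approx(2.0, abs=1e-12)

    def test_sphere_cone_tangency(self):
        """Left and right slopes agree at the transition distance."""
        tip = build_tip(10.0, 20.0)
        d_t = tip.transition_d
        eps = 1e-7
        left = (tip.z(d_t) - tip.z(d_t - eps)) / eps
        right = (tip.z(d_t + eps) - tip.z(d_t)) / eps
        assert abs(left - right) < 1e-5

    @pytest.mark.parametrize("radius,angle", [(0.0, 18.0), (-1.0, 18.0),
                                              (5.0, 0.0), (5.0, 90.0)])
    def test_invalid_geometry_rejected(self, radius, angle):
        with pytest.raises(ValueError):
            build_tip(radius, angle)

    def test_reach_inverts_profile(self):
        tip = build_tip(8.0, 18.0)
        h = np.linspace(0.01, 30.0, 50)
        np.testing.assert_allclose(tip.z(tip.reach(h)), h, atol=1e-9)


class TestSimulateTopograph:
    def test_flat_slab_constant_height(self, tip5):
        # slab sampled on the pixel lattice: image equals h on the footprint
        xs, ys = np.meshgrid(np.arange(0.0, 10.0, 1.0), np.arange(0.0, 10.0, 1.0))
        pts = np.column_stack([xs.ravel(), ys.ravel(), np.full(xs.size, 3.0)])
        img = simulate_topograph(
            SurfaceCloud(vertices=pts), tip5, 1.0,
            grid_shape=(22, 22), grid_origin=(-6.0, -6.0), densify=False,
        )
        np.testing.assert_allclose(img.heights[6:16, 6:16], 3.0, atol=1e-12)
        # dilated footprint: nonzero beyond the slab edge, zero far away
        assert img.heights[6, 3] > 0.0
        assert img.heights.min() == 0.0

    def test_spike_footprint_matches_sphere_contact(self):
        # single spike height 5, spherical tip R=10:
        # footprint radius sqrt(h (2R - h)) = sqrt(75) ~ 8.66 nm
        tip = build_tip(10.0, 18.0)
        pts = np.array([[0.0, 0.0, 5.0], [0.0, 0.1, 0.0], [0.1, 0.0, 0.0],
                        [-0.1, 0.0, 0.0]])
        img = simulate_topograph(SurfaceCloud(vertices=pts), tip, 0.25,
                                 grid_shape=(81, 81), grid_origin=(-10.0, -10.0),
                                 densify=False)
        xs = img.x0 + np.arange(img.shape[1]) * 0.25
        ys = img.y0 + np.arange(img.shape[0]) * 0.25
        gx, gy = np.meshgrid(xs, ys)
        r = np.hypot(gx, gy)
        nz = img.heights > 1e-12
        assert img.heights.max() == pytest.approx(5.0, abs=1e-12)
        assert r[nz].max() == pytest.approx(np.sqrt(75.0), abs=0.3)

    def test_equals_brute_force_oracle(self, tip5):
        """Pixel-wise equality with the per-pixel contact-point scan on
        random rough surfaces."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = rng.integers(150, 350)
            pts = np.column_stack([
                rng.uniform(0, 12, n), rng.uniform(0, 12, n), rng.uniform(0, 6, n)
            ])
            img = simulate_topograph(SurfaceCloud(vertices=pts), tip5, 0.9,
                                     densify=False)
            oracle = brute_force_topograph(pts, tip5, 0.9, img.shape,
                                           (img.x0, img.y0))
            assert np.abs(img.heights - oracle).max() <= 1e-9

    def test_dilation_never_under_reports(self, tip5):
        rng = np.random.default_rng(5)
        pts = np.column_stack([rng.uniform(2, 10, 300), rng.uniform(2, 10, 300),
                               rng.uniform(0, 5, 300)])
        img = simulate_topograph(SurfaceCloud(vertices=pts), tip5, 1.0,
                                 densify=False)
        xs = img.x0 + np.arange(img.shape[1]) * 1.0
        ys = img.y0 + np.arange(img.shape[0]) * 1.0
        # each surface point's true height <= image at the covering pixel
        for p in pts[::7]:
            j = int(round((p[0] - img.x0)))
            i = int(round((p[1] - img.y0)))
            d = np.hypot(xs[j] - p[0], ys[i] - p[1])
            assert img.heights[i, j] >= p[2] - tip5.z(d) - 1e-12

    def test_monotone_in_tip_radius(self):
        rng = np.random.default_rng(6)
        pts = np.column_stack([rng.uniform(0, 10, 200), rng.uniform(0, 10, 200),
                               rng.uniform(0, 5, 200)])
        surf = SurfaceCloud(vertices=pts)
        shape, origin = None, None
        prev = None
        for radius in (1.0, 2.0, 5.0, 10.0):
            img = simulate_topograph(surf, build_tip(radius), 1.0,
                                     grid_shape=shape, grid_origin=origin,
                                     densify=False)
            if shape is None:
                shape, origin = img.shape, (img.x0, img.y0)
            if prev is not None:
                assert np.all(img.heights >= prev - 1e-12)
            prev = img.heights

    def test_morphological_sandwich(self, ellipse_topograph, tip5):
        """opening <= image <= closing, pixel-wise."""
        img = ellipse_topograph
        eroded = erode_topograph(img, tip5)
        opened = simulate_point_redilation(eroded, tip5)
        assert np.all(opened.heights <= img.heights + 1e-9)
        # erosion of the re-dilated surface returns the eroded image
        re_eroded = erode_topograph(opened, tip5)
        np.testing.assert_allclose(re_eroded.heights, eroded.heights, atol=1e-6)


def simulate_point_redilation(img: HeightMap, tip: TipModel) -> HeightMap:
    """Dilate a height raster by the tip (treat pixels as surface points)."""
    ny, nx = img.shape
    xs = img.x0 + np.arange(nx) * img.pixel_size_nm
    ys = img.y0 + np.arange(ny) * img.pixel_size_nm
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel(), img.heights.ravel()])
    return simulate_topograph(
        SurfaceCloud(vertices=pts), tip, img.pixel_size_nm,
        grid_shape=img.shape, grid_origin=(img.x0, img.y0), densify=False,
    )


class TestEstimateTipRadius:
    @pytest.mark.parametrize("radius", [2.0, 5.0, 10.0, 20.0])
    def test_simulate_then_recover_within_5pct(self, radius):
        pts = cylinder_surface(3.5, 40.0, axis="y")
        img = simulate_topograph(SurfaceCloud(vertices=pts), build_tip(radius),
                                 0.5, densify=False)
        est = estimate_tip_radius(img)
        assert abs(est - radius) / radius < 0.05

    def test_near_zero_tip_limit(self):
        pts = cylinder_surface(3.5, 40.0, axis="y")
        img = simulate_topograph(SurfaceCloud(vertices=pts), build_tip(0.1),
                                 0.5, densify=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert estimate_tip_radius(img) < 1.0


class TestOptimizePeriodicity:
    def test_self_match(self, ellipse_topograph):
        scale, out, corr = optimize_periodicity(ellipse_topograph,
                                                ellipse_topograph)
        assert scale == pytest.approx(1.0, abs=0.01)
        assert corr == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("s_true", [0.7, 1.0, 1.3])
    def test_planted_scale_recovered(self, ellipse_topograph, s_true):
        ny = ellipse_topograph.heights.shape[0]
        ny_d = int(ny * s_true * 0.8)
        data = HeightMap(
            heights=_resample_y(ellipse_topograph.heights, s_true, ny_d),
            pixel_size_nm=1.0,
        )
        scale, _, _ = optimize_periodicity(ellipse_topograph, data)
        assert scale == pytest.approx(s_true, abs=0.02)

    def test_out_of_bounds_scale_clamped_with_warning(self, ellipse_topograph):
        ny = ellipse_topograph.heights.shape[0]
        data = HeightMap(
            heights=_resample_y(ellipse_topograph.heights, 3.0, int(ny * 1.5)),
            pixel_size_nm=1.0,
        )
        with pytest.warns(BoundaryWarning):
            scale, _, _ = optimize_periodicity(ellipse_topograph, data)
        assert scale == pytest.approx(2.0, abs=1e-9)

    def test_flat_data_rejected(self, ellipse_topograph):
        flat = HeightMap(heights=np.zeros((40, 20)), pixel_size_nm=1.0)
        with pytest.raises(UndefinedScoreError):
            optimize_periodicity(ellipse_topograph, flat)


class TestHeightMapIO:
    def test_tsv_round_trip_bit_exact(self, tmp_path, ellipse_topograph):
        path = tmp_path / "img.tsv"
        save_heightmap_tsv(ellipse_topograph, path)
        back = load_heightmap_tsv(path)
        np.testing.assert_array_equal(back.heights, ellipse_topograph.heights)
        assert back.pixel_size_nm == ellipse_topograph.pixel_size_nm

    def test_tiff_round_trip(self, tmp_path, ellipse_topograph):
        path = tmp_path / "img.tif"
        save_heightmap_tiff(ellipse_topograph, path)
        back = load_heightmap_tiff(path, pixel_size_nm=1.0)
        np.testing.assert_allclose(back.heights, ellipse_topograph.heights,
                                   atol=1e-5)
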
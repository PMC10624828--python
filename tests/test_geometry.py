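"""Geometry: contouring, ellipse fitting, circumference, axes, depths."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from fetalbiom.errors import AnisotropicSpacingError, DegenerateFitError, EmptyStructureError
from fetalbiom.geometry import (
    EllipseParams,
    ellipse_circumference,
    fit_ellipse_direct,
    outer_contour,
    principal_axis,
    px_to_cm,
    vertical_depth,
)
from fetalbiom.imaging_io import LabelMask

from conftest import ellipse_points, random_blob


def quadrature_perimeter(a, b):
    """Independent oracle: 4a * integral_0^{pi/2} sqrt(1 - e^2 sin^2 t) dt."""
    e2 = 1.0 - (b / a) ** 2
    val, _ = quad(lambda t: math.sqrt(1.0 - e2 * math.sin(t) ** 2), 0.0, math.pi / 2.0,
                  epsabs=1e-14, epsrel=1e-14)
    return 4.0 * a * val


class TestOuterContour:
    def test_filled_square_bbox_within_half_pixel(self):
        grid = np.zeros((40, 40), dtype=bool)
        grid[10:31, 5:26] = True  # 21x21 square
        contour = outer_contour(LabelMask(grid, "brain"))
        assert contour[:, 0].min() == pytest.approx(9.5, abs=0.5)
        assert contour[:, 0].max() == pytest.approx(30.5, abs=0.5)
        assert contour[:, 1].min() == pytest.approx(4.5, abs=0.5)
        assert contour[:, 1].max() == pytest.approx(25.5, abs=0.5)

    def test_largest_component_wins(self):
        grid = np.zeros((60, 60), dtype=bool)
        grid[10:35, 10:30] = True  # 500 px
        grid[50:52, 50:53] = True  # small satellite
        contour = outer_contour(LabelMask(grid, "abdomen"))
        assert contour[:, 0].max() < 40  # satellite not contoured

    def test_single_pixel_too_small(self):
        grid = np.zeros((20, 20), dtype=bool)
        grid[5, 5] = True
        with pytest.raises(EmptyStructureError):
            outer_contour(LabelMask(grid, "brain"))

    def test_empty_mask_errors(self):
        with pytest.raises(EmptyStructureError):
            outer_contour(LabelMask(np.zeros((20, 20), dtype=bool), "brain"))


class TestFitEllipseDirect:
    def test_circle_recovered_exactly(self):
        pts = ellipse_points(10, 10, 0, 50, 50, n=360)
        e = fit_ellipse_direct(pts)
        assert e.center_row == pytest.approx(50, abs=1e-6)
        assert e.center_col == pytest.approx(50, abs=1e-6)
        assert e.semi_major_a == pytest.approx(10, abs=1e-6)
        assert e.semi_minor_b == pytest.approx(10, abs=1e-6)

    @pytest.mark.parametrize("a,b,theta,cr,cc", [
        (80, 50, 30, 120, 100),
        (80, 50, -60, 0, 0),
        (5, 3, 90, 7, 9),
        (100, 99.5, 10, -40, 300),
    ])
    def test_noise_free_recovery_1e6_relative(self, a, b, theta, cr, cc):
        e = fit_ellipse_direct(ellipse_points(a, b, theta, cr, cc))
        assert e.semi_major_a == pytest.approx(a, rel=1e-6)
        assert e.semi_minor_b == pytest.approx(b, rel=1e-6)
        assert abs((e.orientation_deg - theta + 90) % 180 - 90) < 1e-5
        assert e.center_row == pytest.approx(cr, abs=1e-6 * max(1, abs(cr)))
        assert e.center_col == pytest.approx(cc, abs=1e-6 * max(1, abs(cc)))

    def test_noisy_fit_center_error_below_half_pixel(self):
        # Monte-Carlo against the known generating center
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pts = ellipse_points(80, 50, 30, 120, 100, n=100, noise_sd=1.0, rng=rng)
            e = fit_ellipse_direct(pts)
            errs.append(math.hypot(e.center_row - 120, e.center_col - 100))
        assert np.mean(errs) < 0.5

    def test_equivariance_under_translation_and_rotation(self):
        pts = ellipse_points(60, 25, 20, 0, 0, n=80)
        base = fit_ellipse_direct(pts)
        # translation
        shifted = fit_ellipse_direct(pts + np.array([17.0, -9.0]))
        assert shifted.center_row == pytest.approx(base.center_row + 17.0, abs=1e-9)
        assert shifted.center_col == pytest.approx(base.center_col - 9.0, abs=1e-9)
        assert shifted.semi_major_a == pytest.approx(base.semi_major_a, abs=1e-9)
        # rotation by alpha in the (row, col) plane
        alpha = math.radians(25.0)
        rot = np.array([[math.cos(alpha), -math.sin(alpha)],
                        [math.sin(alpha), math.cos(alpha)]])
        rotated = fit_ellipse_direct(pts @ rot)
        assert rotated.semi_major_a == pytest.approx(base.semi_major_a, abs=1e-9)
        assert rotated.semi_minor_b == pytest.approx(base.semi_minor_b, abs=1e-9)
        got = (rotated.orientation_deg - base.orientation_deg) % 180.0
        assert got == pytest.approx(25.0, abs=1e-6)

    def test_too_few_points(self):
        with pytest.raises(DegenerateFitError):
            fit_ellipse_direct(np.array([[0, 0], [1, 1], [2, 2], [3, 3]]))

    def test_collinear_points_degenerate(self):
        pts = np.column_stack([np.arange(20.0), 2.0 * np.arange(20.0)])
        with pytest.raises(DegenerateFitError):
            fit_ellipse_direct(pts)


class TestCircumference:
    def test_circle_closed_form(self):
        e = EllipseParams(0, 0, 7.0, 7.0, 0.0)
        assert ellipse_circumference(e) == pytest.approx(2 * math.pi * 7.0, rel=1e-12)

    def test_flat_limit_is_4a(self):
        e = EllipseParams(0, 0, 2.0, 1e-12, 0.0)
        assert ellipse_circumference(e) == pytest.approx(8.0, rel=1e-9)

    def test_matches_quadrature_oracle(self):
        e = EllipseParams(0, 0, 2.0, 1.0, 0.0)
        assert ellipse_circumference(e) == pytest.approx(
            quadrature_perimeter(2.0, 1.0), rel=1e-10
        )

    def test_invariant_under_pose_and_monotone_in_axes(self):
        base = ellipse_circumference(EllipseParams(0, 0, 50, 30, 0.0))
        moved = ellipse_circumference(EllipseParams(400, -100, 50, 30, 77.0))
        assert moved == base
        assert ellipse_circumference(EllipseParams(0, 0, 51, 30, 0.0)) > base
        assert ellipse_circumference(EllipseParams(0, 0, 50, 31, 0.0)) > base


class TestPrincipalAxis:
    def test_axis_aligned_rectangle(self):
        grid = np.zeros((80, 100), dtype=bool)
        grid[30:41, 20:81]= True  # 61 cols x 11 rows
        ax = principal_axis(LabelMask(grid, "femur"))
        assert ax.length_px == pytest.approx(60.0, abs=1e-6)
        assert ax.angle_deg == pytest.approx(0.0, abs=1e-6)

    def test_rotated_rectangle_length_and_angle(self):
        # rasterize a 61x11 rectangle rotated by 30 degrees
        rows, cols = np.mgrid[0:200, 0:200]
        th = math.radians(30.0)
        u = (cols - 100) * math.cos(th) + (rows - 100) * math.sin(th)
        v = -(cols - 100) * math.sin(th) + (rows - 100) * math.cos(th)
        grid = (np.abs(u) <= 30) & (np.abs(v) <= 5)
        ax = principal_axis(LabelMask(grid, "femur"))
        assert ax.length_px == pytest.approx(60.0, abs=1.0)
        assert ax.angle_deg == pytest.approx(30.0, abs=2.0)

    def test_crossed_bars_match_bruteforce_min_area_box(self):
        # exhaustive oracle: sweep candidate box orientations over hull
        # edges (the min-area rectangle is flush with one of them)
        grid = np.zeros((81, 81), dtype=bool)
        grid[40, 5:76] = True   # long horizontal bar
        grid[25:56, 40] = True  # short vertical bar
        pts = np.argwhere(grid).astype(float)
        best = None
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                d = pts[j] - pts[i]
                norm = math.hypot(*d)
                if norm == 0:
                    continue
                u = d / norm
                v = np.array([-u[1], u[0]])
                pu = pts @ u
                pv = pts @ v
                du, dv = pu.max() - pu.min(), pv.max() - pv.min()
                area = du * dv
                if best is None or area < best[0] - 1e-9:
                    best = (area, max(du, dv))
        ax = principal_axis(LabelMask(grid, "femur"))
        assert ax.length_px == pytest.approx(best[1], abs=1e-6)

    def test_symmetric_plus_is_deterministic(self):
        grid = np.zeros((61, 61), dtype=bool)
        grid[30, 10:51] = True
        grid[10:51, 30] = True
        ax1 = principal_axis(LabelMask(grid, "femur"))
        ax2 = principal_axis(LabelMask(grid, "femur"))
        assert ax1 == ax2
        assert abs(ax1.angle_deg) == pytest.approx(45.0, abs=1e-6)

    def test_translation_invariance_and_rotation_covariance(self):
        rows, cols = np.mgrid[0:128, 0:128]
        base = (np.abs(cols - 60) <= 25) & (np.abs(rows - 60) <= 4)
        ax0 = principal_axis(LabelMask(base, "femur"))
        shifted = np.zeros_like(base)
        shifted[10:, 5:] = base[:-10, :-5]
        ax1 = principal_axis(LabelMask(shifted, "femur"))
        assert ax1.length_px == pytest.approx(ax0.length_px, abs=1e-9)
        th = math.radians(20.0)
        u = (cols - 60) * math.cos(th) + (rows - 60) * math.sin(th)
        v = -(cols - 60) * math.sin(th) + (rows - 60) * math.cos(th)
        rot = (np.abs(u) <= 25) & (np.abs(v) <= 4)
        ax2 = principal_axis(LabelMask(rot, "femur"))
        assert ax2.angle_deg == pytest.approx(ax0.angle_deg + 20.0, abs=2.0)

    def test_empty_mask_errors(self):
        with pytest.raises(EmptyStructureError):
            principal_axis(LabelMask(np.zeros((20, 20), dtype=bool), "femur"))


class TestVerticalDepth:
    def test_row_extent(self):
        grid = np.zeros((80, 40), dtype=bool)
        grid[10:61, 5:20] = True
        d = vertical_depth(LabelMask(grid, "af_pocket"))
        assert d.depth_px == 50.0
        assert (d.top_row, d.bottom_row) == (10.0, 60.0)

    def test_single_row_depth_zero(self):
        grid = np.zeros((20, 20), dtype=bool)
        grid[7, 3:9] = True
        assert vertical_depth(LabelMask(grid, "af_pocket")).depth_px == 0.0

    def test_l_shape_uses_bounding_box_not_chord(self):
        grid = np.zeros((50, 50), dtype=bool)
        grid[10:20, 10:12] = True   # upper arm, rows 10-19
        grid[35:45, 10:30] = True   # lower slab, rows 35-44
        d = vertical_depth(LabelMask(grid, "af_pocket"))
        # full row extent 34, even though the longest single chord is 9
        assert d.depth_px == 34.0

    def test_matches_bruteforce_on_random_blobs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            mask = random_blob(rng)
            d = vertical_depth(mask)
            rows = np.nonzero(mask.grid.any(axis=1))[0]
            assert d.depth_px == float(rows.max() - rows.min())


class TestPxToCm:
    def test_basic_product(self):
        assert px_to_cm(50, 0.05, 0.05) == pytest.approx(2.5)
        assert px_to_cm(0, 0.05, 0.05) == 0.0
        assert px_to_cm(10, 0.05, 0.07, axis="row") == pytest.approx(0.5)
        assert px_to_cm(10, 0.05, 0.07, axis="col") == pytest.approx(0.7)

    def test_anisotropic_isotropic_conversion_rejected(self):
        with pytest.raises(AnisotropicSpacingError):
            px_to_cm(10, 0.05, 0.06, axis="isotropic")
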
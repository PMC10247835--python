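"""Unit and property tests for the cross-section geometry layer."""

import math

import numpy as np
import pytest
import shapely
from hypothesis import given, settings, strategies as st
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from conftest import star_polygon
from rotadebulk.geometry import (
    CalciumArc,
    GeometryError,
    Point2D,
    actual_region,
    angular_extent,
    circle_polygon,
    lumen_diameters,
    make_device_circle,
    min_clearance,
    overlap_region,
    predicted_region,
    region_area,
    validate_contour,
)

ORIGIN = Point2D(0.0, 0.0)


def sector(r_in, r_out, a0_deg, a1_deg, steps=200):
    """Annular sector polygon spanning polar angles [a0, a1] degrees."""
    a = np.radians(np.linspace(a0_deg, a1_deg, steps))
    outer = np.c_[r_out * np.cos(a), r_out * np.sin(a)]
    inner = np.c_[r_in * np.cos(a[::-1]), r_in * np.sin(a[::-1])]
    return Polygon(np.vstack([outer, inner]))


class TestDeviceCircle:
    @pytest.mark.parametrize("diameter,expected_area", [
        (2.0, math.pi * 1.0 ** 2),
        (0.9, math.pi * 0.45 ** 2),
    ])
    def test_polygonized_area(self, diameter, expected_area):
        circle = make_device_circle(ORIGIN, diameter)
        assert circle.polygon().area == pytest.approx(expected_area, rel=1e-3)

    def test_vertex_count_controls_accuracy(self):
        c = make_device_circle(ORIGIN, 2.0)
        err360 = math.pi - c.polygon(360).area
        err36 = math.pi - c.polygon(36).area
        assert 0 < err360 < 2e-4 * math.pi  # < 0.02 %
        assert err360 < err36

    @pytest.mark.parametrize("diameter", [0.0, -1.0])
    def test_nonpositive_diameter_rejected(self, diameter):
        with pytest.raises(GeometryError):
            make_device_circle(ORIGIN, diameter)


class TestPredictedRegion:
    def test_burr_equal_to_lumen_gives_empty(self):
        lumen = circle_polygon(ORIGIN, 1.0)
        burr = make_device_circle(ORIGIN, 2.0)
        assert region_area(predicted_region(burr, lumen)) == pytest.approx(0.0, abs=1e-9)

    def test_offset_burr_matches_two_circle_lens_formula(self):
        # unit-radius lumen at origin, unit-radius burr centred at (0.5, 0):
        # wall overlap = circle area minus the two-circle lens
        r, d = 1.0, 0.5
        lens = 2 * r * r * math.acos(d / (2 * r)) - (d / 2) * math.sqrt(4 * r * r - d * d)
        lumen = circle_polygon(ORIGIN, r, 720)
        burr = make_device_circle(Point2D(d, 0.0), 2 * r)
        area = region_area(predicted_region(burr, lumen, n_vertices=720))
        assert area == pytest.approx(math.pi - lens, abs=1e-3)

    def test_burr_strictly_inside_lumen_gives_zero(self):
        lumen = circle_polygon(ORIGIN, 2.0)
        burr = make_device_circle(Point2D(0.2, 0.1), 1.25)
        assert region_area(predicted_region(burr, lumen)) == 0.0

    def test_partition_of_burr_circle(self):
        # wall part + lumen part = whole burr circle (polygonization tolerance)
        rng = np.random.default_rng(5)
        for _ in range(10):
            lumen = validate_contour(star_polygon(rng, r_lo=0.8, r_hi=1.6))
            burr = make_device_circle(Point2D(*rng.uniform(-0.5, 0.5, 2)), 1.75)
            wall = region_area(predicted_region(burr, lumen))
            inside = burr.polygon().intersection(lumen).area
            assert wall + inside == pytest.approx(burr.polygon().area, abs=1e-9)


class TestActualRegion:
    def test_no_change_gives_zero(self):
        lumen = circle_polygon(ORIGIN, 1.0)
        assert region_area(actual_region(lumen, lumen)) == pytest.approx(0.0, abs=1e-12)

    def test_concentric_annulus_closed_form(self):
        pre = circle_polygon(ORIGIN, 1.0, 720)
        post = circle_polygon(ORIGIN, 1.1, 720)
        expected = math.pi * (1.1 ** 2 - 1.0 ** 2)
        assert region_area(actual_region(pre, post)) == pytest.approx(expected, abs=1e-3)

    def test_constructed_notch_recovered(self):
        pre = circle_polygon(ORIGIN, 1.0, 720)
        notch = circle_polygon((1.0, 0.0), 0.5, 720)
        post = pre.union(notch)
        q = notch.difference(pre).area
        assert region_area(actual_region(pre, post)) == pytest.approx(q, rel=1e-9)

    def test_lumen_loss_not_counted_as_ablation(self):
        pre = circle_polygon(ORIGIN, 1.0)
        post = circle_polygon(Point2D(0.3, 0.0), 1.0)  # shifted: gain and loss
        a = actual_region(pre, post)
        assert region_area(a) == pytest.approx(post.difference(pre).area, rel=1e-9)


class TestOverlapAndArea:
    def test_overlap_identity_and_disjoint(self):
        sq = shapely.MultiPolygon([Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])])
        far = shapely.MultiPolygon([Polygon([(5, 5), (6, 5), (6, 6), (5, 6)])])
        assert region_area(overlap_region(sq, sq)) == pytest.approx(1.0)
        assert region_area(overlap_region(sq, far)) == 0.0

    def test_offset_unit_squares(self):
        a = shapely.MultiPolygon([Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])])
        b = shapely.MultiPolygon([Polygon([(0.5, 0), (1.5, 0), (1.5, 1), (0.5, 1)])])
        assert region_area(overlap_region(a, b)) == pytest.approx(0.5)

    def test_area_matches_shoelace_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            poly = star_polygon(rng)
            xy = np.asarray(poly.exterior.coords)
            x, y = xy[:-1, 0], xy[:-1, 1]
            shoelace = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
            assert region_area(poly) == pytest.approx(shoelace, rel=1e-9)


class TestAngularExtent:
    def test_full_annulus(self):
        outer = circle_polygon(ORIGIN, 4.0)
        annulus = outer.difference(circle_polygon(ORIGIN, 2.0))
        assert angular_extent(annulus, ORIGIN) == pytest.approx(360.0)

    def test_sector_span(self):
        assert angular_extent(sector(1.0, 2.0, 30, 90), ORIGIN) == pytest.approx(60.0, abs=0.1)

    def test_wraparound_union(self):
        region = shapely.MultiPolygon([sector(1, 2, 0, 40), sector(1, 2, 350, 360)])
        assert angular_extent(region, ORIGIN) == pytest.approx(50.0, abs=0.1)

    def test_center_inside_region_rejected(self):
        disc = circle_polygon(ORIGIN, 2.0)
        with pytest.raises(GeometryError):
            angular_extent(disc, ORIGIN)

    def test_empty_region_is_zero(self):
        assert angular_extent(shapely.MultiPolygon([]), ORIGIN) == 0.0

    def test_against_ray_sampling_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            spans = [(rng.uniform(0, 360), rng.uniform(5, 120)) for _ in range(2)]
            region = shapely.unary_union(
                [sector(1, 2, a, a + w) for a, w in spans])
            ang = np.radians(np.arange(0, 360, 0.1))
            rays = shapely.linestrings(np.stack([
                np.zeros((len(ang), 2)),
                np.c_[10 * np.cos(ang), 10 * np.sin(ang)]], axis=1))
            oracle = shapely.intersects(region, rays).sum() * 0.1
            assert angular_extent(region, ORIGIN) == pytest.approx(oracle, abs=0.5)


class TestMinClearance:
    def test_circle_circle_exact(self):
        cath = make_device_circle(ORIGIN, 0.9, "catheter")
        wire = make_device_circle(Point2D(2.0, 0.0), 0.229, "wire")
        assert min_clearance(cath, wire) == pytest.approx(2.0 - 0.45 - 0.1145)

    def test_overlapping_circles_clamp_to_zero(self):
        a = make_device_circle(ORIGIN, 1.0)
        b = make_device_circle(Point2D(0.3, 0.0), 1.0)
        assert min_clearance(a, b) == 0.0

    def test_contained_circle_is_contact(self):
        big = make_device_circle(ORIGIN, 2.0)
        small = make_device_circle(Point2D(0.1, 0.0), 0.2)
        assert min_clearance(big, small) == 0.0

    def test_circle_inside_polygon_matches_boundary_sampling(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            lumen = validate_contour(star_polygon(rng, r_lo=1.0, r_hi=2.0))
            dev = make_device_circle(Point2D(*rng.uniform(-0.3, 0.3, 2)), 0.5)
            # oracle: dense boundary samples of both surfaces
            t = np.linspace(0, lumen.exterior.length, 20000)
            wall = np.array([lumen.exterior.interpolate(d).coords[0] for d in t])
            a = np.linspace(0, 2 * np.pi, 5000)
            circ = np.c_[dev.center.x + dev.radius * np.cos(a),
                         dev.center.y + dev.radius * np.sin(a)]
            oracle = cKDTree(wall).query(circ)[0].min()
            assert min_clearance(dev, lumen) == pytest.approx(oracle, abs=1e-3)

    @given(st.floats(0.1, 3.0), st.floats(0.1, 3.0),
           st.floats(-5, 5), st.floats(-5, 5))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_symmetry(self, d1, d2, x, y):
        a = make_device_circle(ORIGIN, d1)
        b = make_device_circle(Point2D(x, y), d2)
        assert min_clearance(a, b) == pytest.approx(min_clearance(b, a))


class TestLumenDiameters:
    def test_circle(self):
        mind, meand, area = lumen_diameters(circle_polygon(ORIGIN, 1.0, 720))
        assert mind == pytest.approx(2.0, abs=1e-3)
        assert meand == pytest.approx(2.0, abs=1e-3)
        assert area == pytest.approx(math.pi, rel=1e-3)

    def test_ellipse_against_dense_oracle(self):
        a, b = 1.5, 1.0
        t = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        ellipse = Polygon(np.c_[a * np.cos(t), b * np.sin(t)])
        mind, meand, _ = lumen_diameters(ellipse)
        assert mind == pytest.approx(2.0, abs=0.01)
        # oracle: chord lengths at 0.1 degree steps
        angs = np.radians(np.arange(0, 180, 0.1))
        chords = 2.0 / np.sqrt((np.cos(angs) / a) ** 2 + (np.sin(angs) / b) ** 2)
        assert meand == pytest.approx(chords.mean(), rel=5e-3)

    def test_degenerate_contour_rejected(self):
        with pytest.raises(GeometryError):
            lumen_diameters(Polygon([(0, 0), (1e-4, 0), (1e-4, 1e-4)]))


class TestCalciumArc:
    def test_span_wraps(self):
        assert CalciumArc(350, 20).span_deg == pytest.approx(30.0)
        assert CalciumArc(0, 0).span_deg == 360.0

    def test_negative_depth_rejected(self):
        with pytest.raises(GeometryError):
            CalciumArc(0, 90, min_depth_um=-1)
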
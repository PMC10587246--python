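"""Geometry: projection, spherical areas, field layout, fractional overlap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point, Polygon

from oracles import mc_field_fractions, mc_spherical_area

from retquant.geometry import (
    DEFAULT_EYE_RADIUS_MM,
    DEFAULT_MM_PER_DEGREE,
    InvalidGeometryError,
    LandmarkError,
    build_field_layout,
    field_overlap,
    polygon_area_mm2,
    project_to_plane,
    spherical_area_mm2,
    unproject_from_plane,
)


class TestProjection:
    def test_fovea_maps_to_origin(self):
        assert project_to_plane((0.0, 0.0)) == (0.0, 0.0)

    def test_round_trip_identity(self, rng):
        pts = rng.uniform(-90, 90, size=(1000, 2))
        for p in pts:
            x, y = project_to_plane(p)
            back = unproject_from_plane((x, y))
            # tolerance stated in mm on the plane; check both directions
            assert math.hypot(back[0] - p[0], back[1] - p[1]) < 1e-9 / DEFAULT_MM_PER_DEGREE

    def test_antipode_rejected(self):
        with pytest.raises(ValueError):
            project_to_plane((180.0, 0.0))

    def test_conformal_scale_at_pole(self):
        # near the pole the projection is locally isometric up to 2R tan(e/2) ~ R*e
        x, y = project_to_plane((1e-4, 0.0))
        assert x == pytest.approx(1e-4 * DEFAULT_MM_PER_DEGREE, rel=1e-6)


class TestSphericalArea:
    @pytest.mark.parametrize("eps_deg", [0.5, 5.0, 10.0, 40.0])
    def test_cap_closed_form(self, eps_deg):
        """A chart circle of radius eps is a spherical cap: 2*pi*R^2*(1-cos eps)."""
        circle = Point(0, 0).buffer(eps_deg, quad_segs=256)
        r = DEFAULT_EYE_RADIUS_MM
        exact = 2 * math.pi * r * r * (1 - math.cos(math.radians(eps_deg)))
        assert polygon_area_mm2(circle) == pytest.approx(exact, rel=1e-3)

    def test_small_circle_flat_limit(self):
        circle = Point(0, 0).buffer(0.5, quad_segs=128)
        flat = math.pi * (0.5 * DEFAULT_MM_PER_DEGREE) ** 2
        assert polygon_area_mm2(circle) == pytest.approx(flat, rel=1e-2)

    def test_degenerate_polygon_zero(self):
        degenerate = Polygon([(3, 3), (3, 3), (3, 3), (3, 3)])
        assert polygon_area_mm2(degenerate) == 0.0

    def test_self_intersecting_rejected(self):
        bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])
        with pytest.raises(InvalidGeometryError):
            polygon_area_mm2(bowtie)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_monte_carlo_at_eccentricity(self, seed):
        """Corrected-projection areas agree with spherical MC integration."""
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-5, 5, size=(12, 2)) + np.array([28.0, 28.0])  # ~40 deg ecc
        poly = Polygon(pts).convex_hull
        mc = mc_spherical_area(poly, DEFAULT_MM_PER_DEGREE, n=600_000, seed=seed + 10)
        assert polygon_area_mm2(poly) == pytest.approx(mc, rel=5e-3)

    def test_scale_linearity(self):
        """Doubling the mm-per-degree scale quadruples every area."""
        poly = Point(10, -5).buffer(3, quad_segs=32)
        a1 = spherical_area_mm2(poly, DEFAULT_MM_PER_DEGREE)
        a2 = spherical_area_mm2(poly, 2 * DEFAULT_MM_PER_DEGREE)
        assert a2 == pytest.approx(4 * a1, rel=1e-12)


class TestFieldLayout:
    def test_seven_equal_fields_on_landmarks(self, od_layout):
        assert len(od_layout.fields) == 7
        radii = {f.radius_deg for f in od_layout.fields}
        assert radii == {15.0}
        assert tuple(od_layout.fields[0].center) == (-15.5, 1.5)  # F1 = disc
        assert tuple(od_layout.fields[1].center) == (0.0, 0.0)  # F2 = fovea

    def test_field3_nasal_edge_at_fovea(self, od_layout):
        f3 = od_layout.fields[2]
        # F3 center sits one radius temporal of the fovea along the axis
        assert math.hypot(*f3.center) == pytest.approx(15.0, abs=1e-9)
        assert f3.center.longitude > 0  # temporal side for OD

    def test_os_is_longitude_mirror_of_od(self):
        od = build_field_layout((-15.5, 1.5), (0, 0), "OD")
        os_ = build_field_layout((15.5, 1.5), (0, 0), "OS")
        for f_od, f_os in zip(od.fields, os_.fields):
            assert f_os.center.longitude == pytest.approx(-f_od.center.longitude)
            assert f_os.center.latitude == pytest.approx(f_od.center.latitude)

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(LandmarkError):
            build_field_layout((0, 0), (0, 0), "OD")

    def test_laterality_inconsistent_with_disc_side(self):
        with pytest.raises(LandmarkError):
            build_field_layout((15.5, 1.5), (0, 0), "OD")  # disc temporal: wrong

    def test_union_area_matches_monte_carlo(self, od_layout):
        mc = mc_spherical_area(od_layout.union, od_layout.mm_per_degree, n=1_000_000, seed=77)
        assert od_layout.union_area_mm2 == pytest.approx(mc, rel=5e-3)


class TestFieldOverlap:
    def test_wholly_inside_one_field(self, od_layout):
        poly = Point(0, 0).buffer(2, quad_segs=16)  # deep inside F2
        res = field_overlap(poly, od_layout)
        assert res.per_field_fraction[1] == pytest.approx(1.0, abs=1e-9)
        assert res.outside_fraction == 0.0

    def test_wholly_outside_union(self, od_layout):
        poly = Point(80, 80).buffer(3, quad_segs=16)
        res = field_overlap(poly, od_layout)
        assert res.outside_fraction == 1.0
        assert res.per_field_fraction.sum() == 0.0

    def test_straddling_matches_monte_carlo(self, od_layout):
        poly = Point(7.5, 0).buffer(5, quad_segs=32)  # F2/F3 boundary zone
        res = field_overlap(poly, od_layout)
        mc, mc_out = mc_field_fractions(poly, od_layout, n=200_000, seed=3)
        assert np.allclose(res.per_field_fraction, mc, atol=0.01)
        assert res.outside_fraction == pytest.approx(mc_out, abs=0.01)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        cx=st.floats(-60, 60),
        cy=st.floats(-60, 60),
        radius=st.floats(0.5, 12),
    )
    def test_partition_invariant(self, od_layout, cx, cy, radius):
        """Per-field fractions plus the outside fraction always sum to one."""
        poly = Point(cx, cy).buffer(radius, quad_segs=8)
        res = field_overlap(poly, od_layout)
        assert res.per_field_fraction.sum() + res.outside_fraction == pytest.approx(
            1.0, abs=1e-9
        )
        assert (res.per_field_area >= 0).all()

    def test_mirror_equivariance(self):
        """Mirroring the eye mirrors the lesion onto the same field indices."""
        od = build_field_layout((-15.5, 1.5), (0, 0), "OD")
        os_ = build_field_layout((15.5, 1.5), (0, 0), "OS")
        poly = Point(9, 4).buffer(6, quad_segs=16)
        mirrored = Point(-9, 4).buffer(6, quad_segs=16)
        res_od = field_overlap(poly, od)
        res_os = field_overlap(mirrored, os_)
        assert np.allclose(res_od.per_field_fraction, res_os.per_field_fraction, atol=1e-9)
        assert res_od.outside_fraction == pytest.approx(res_os.outside_fraction, abs=1e-9)

    def test_zero_area_polygon_reported_outside(self, od_layout):
        degenerate = Polygon([(1, 1), (1, 1), (1, 1), (1, 1)])
        res = field_overlap(degenerate, od_layout)
        assert res.outside_fraction == 1.0
        assert res.total_area_mm2 == 0.0
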
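"""ETDRS seven-standard-field geometry on a spherical eye model.

The retina is modeled as a sphere of radius ``R``.  Annotations live in an
azimuthal-equidistant chart about the fovea: a point at chart position
``(lon, lat)`` degrees lies at central angle ``eps = hypot(lon, lat)``
degrees from the fovea (the posterior pole), in the azimuthal direction
``atan2(lat, lon)``.  One chart degree therefore corresponds to a fixed
arc length ``mm_per_degree = R * pi / 180`` on the sphere, which ties the
two scale constants together: the default retinal scale of 0.291 mm/deg
(emmetropic schematic eye) implies a model sphere radius of ~16.67 mm.

Lesion areas are reported on the sphere.  Polygons are defined with
straight edges in the chart; their spherical surface area is obtained by
integrating the equidistant-chart area-correction factor sin(eps)/eps,
which this module does exactly (to quadrature precision) with a
Green's-theorem line integral, so a chart circle of radius ``eps`` has
spherical area 2*pi*R^2*(1 - cos eps) — the spherical-cap closed form.

The stereographic projection used for planar processing maps the sphere
from the anterior pole (the fovea's antipode) onto the plane tangent at
the fovea; it is conformal and invertible, with the familiar local area
magnification sec^4(eps/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import MultiPolygon, Point, Polygon, box
from shapely.geometry.polygon import orient
from shapely.ops import unary_union
from shapely.prepared import prep

DEG = math.pi / 180.0

#: Default retinal scale, mm of retinal arc per degree of visual angle.
DEFAULT_MM_PER_DEGREE = 0.291

#: Model sphere radius consistent with the default scale (mm).
DEFAULT_EYE_RADIUS_MM = DEFAULT_MM_PER_DEGREE / DEG  # ~16.67 mm

#: Default ETDRS field radius (deg): 30-degree-diameter standard fields.
DEFAULT_FIELD_RADIUS_DEG = 15.0

#: Default field-placement table.  Each entry places a field center at
#: ``anchor + radius * (t * temporal_unit + v * superior_unit)`` where the
#: anchor is the disc or fovea landmark.  The defaults encode the classic
#: seven-field arrangement: field 1 on the disc, field 2 on the fovea,
#: field 3 temporal to the fovea with its nasal edge at the fovea, fields
#: 4/5 superior/inferior-temporal and 6/7 superior/inferior-nasal, tangent
#: to the meridians through the disc center.
DEFAULT_FIELD_TABLE: dict[int, tuple[str, float, float]] = {
    1: ("disc", 0.0, 0.0),
    2: ("fovea", 0.0, 0.0),
    3: ("fovea", 1.0, 0.0),
    4: ("disc", 1.0, 1.0),
    5: ("disc", 1.0, -1.0),
    6: ("disc", -1.0, 1.0),
    7: ("disc", -1.0, -1.0),
}


class LandmarkError(ValueError):
    """Disc/fovea landmarks are degenerate or inconsistent with laterality."""


class InvalidGeometryError(ValueError):
    """A lesion polygon is self-intersecting or otherwise invalid."""


class RetinalPoint(tuple):
    """(longitude, latitude) in degrees of visual angle."""

    def __new__(cls, longitude: float, latitude: float):
        return super().__new__(cls, (float(longitude), float(latitude)))

    @property
    def longitude(self) -> float:
        return self[0]

    @property
    def latitude(self) -> float:
        return self[1]


# ---------------------------------------------------------------------------
# Stereographic projection


def project_to_plane(
    p: RetinalPoint | Sequence[float], eye_radius_mm: float = DEFAULT_EYE_RADIUS_MM
) -> tuple[float, float]:
    """Project a retinal point onto the plane tangent at the fovea (mm).

    Azimuthal stereographic projection from the anterior pole: a point at
    central angle ``eps`` maps to planar radius ``2 R tan(eps / 2)``.  The
    fovea maps to the origin.  Raises for the projection antipode
    (``eps >= 180``).
    """
    lon, lat = float(p[0]), float(p[1])
    eps = math.hypot(lon, lat)
    if eps >= 180.0:
        raise ValueError(f"point at eccentricity {eps:.1f} deg is at/beyond the projection antipode")
    if eps == 0.0:
        return (0.0, 0.0)
    rho = 2.0 * eye_radius_mm * math.tan(eps * DEG / 2.0)
    return (rho * lon / eps, rho * lat / eps)


def unproject_from_plane(
    xy: Sequence[float], eye_radius_mm: float = DEFAULT_EYE_RADIUS_MM
) -> RetinalPoint:
    """Inverse of :func:`project_to_plane`."""
    x, y = float(xy[0]), float(xy[1])
    rho = math.hypot(x, y)
    if rho == 0.0:
        return RetinalPoint(0.0, 0.0)
    eps = 2.0 * math.atan(rho / (2.0 * eye_radius_mm)) / DEG
    return RetinalPoint(eps * x / rho, eps * y / rho)


# ---------------------------------------------------------------------------
# Spherical surface area of chart polygons

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(32)
_GL_T = 0.5 * (_GL_NODES + 1.0)  # nodes on [0, 1]
_GL_W = 0.5 * _GL_WEIGHTS


def _h_weight(rho2: np.ndarray) -> np.ndarray:
    """Radial potential h(rho^2) with h + r h' = sinc(k rho), k = pi/180.

    h(rho^2) = 2 (1 - cos(k rho)) / (k rho)^2, smoothly extended to 1 at 0.
    Green's theorem with the field h*(x dy - y dx)/2 then integrates the
    equidistant-chart spherical area element sin(eps)/eps exactly.
    """
    x2 = (DEG * DEG) * rho2
    small = x2 < 1e-12
    x2_safe = np.where(small, 1.0, x2)
    out = 2.0 * (1.0 - np.cos(np.sqrt(x2_safe))) / x2_safe
    return np.where(small, 1.0 - x2 / 12.0, out)


def _ring_signed_area_deg2(coords: np.ndarray) -> float:
    """Signed sphere-weighted area (deg^2 units) of one closed chart ring."""
    p0 = coords[:-1]
    d = coords[1:] - coords[:-1]
    # cross(p(t), p'(t)) is constant along a straight edge: cross(p0, d)
    cross = p0[:, 0] * d[:, 1] - p0[:, 1] * d[:, 0]
    pts = p0[:, None, :] + _GL_T[None, :, None] * d[:, None, :]
    rho2 = pts[..., 0] ** 2 + pts[..., 1] ** 2
    edge_int = _h_weight(rho2) @ _GL_W
    return 0.5 * float(np.dot(cross, edge_int))


def _polygon_sphere_area_deg2(poly: Polygon) -> float:
    poly = orient(poly)  # exterior CCW, holes CW -> signed sum is positive
    total = _ring_signed_area_deg2(np.asarray(poly.exterior.coords))
    for ring in poly.interiors:
        total += _ring_signed_area_deg2(np.asarray(ring.coords))
    return total


def spherical_area_mm2(
    geom: Polygon | MultiPolygon, mm_per_degree: float = DEFAULT_MM_PER_DEGREE
) -> float:
    """Spherical surface area (mm^2) of a chart polygon or multipolygon."""
    if geom.is_empty:
        return 0.0
    if isinstance(geom, MultiPolygon):
        deg2 = sum(_polygon_sphere_area_deg2(g) for g in geom.geoms)
    elif isinstance(geom, Polygon):
        deg2 = _polygon_sphere_area_deg2(geom)
    else:  # GeometryCollection from overlay ops: keep polygonal parts
        deg2 = sum(
            _polygon_sphere_area_deg2(g)
            for g in getattr(geom, "geoms", [])
            if isinstance(g, Polygon)
        )
    return abs(deg2) * mm_per_degree * mm_per_degree


def _as_polygon(poly: Polygon | Sequence[Sequence[float]]) -> Polygon:
    if not isinstance(poly, (Polygon, MultiPolygon)):
        poly = Polygon(poly)
    return poly


def validate_polygon(poly: Polygon | Sequence[Sequence[float]]) -> Polygon:
    """Return the polygon if simple/valid; zero-area degenerates pass through.

    Raises :class:`InvalidGeometryError` for self-intersecting rings.
    """
    poly = _as_polygon(poly)
    if poly.is_empty:
        return poly
    if not poly.is_valid:
        # zero-extent rings (all vertices identical/collinear) are harmless
        # degenerates; anything with spatial extent but invalid topology is not
        if poly.convex_hull.area == 0.0:
            return Polygon()
        raise InvalidGeometryError("polygon is self-intersecting or invalid")
    return poly


def polygon_area_mm2(
    poly: Polygon | Sequence[Sequence[float]],
    eye_radius_mm: float = DEFAULT_EYE_RADIUS_MM,
) -> float:
    """Spherical surface area (mm^2) of a lesion polygon given in chart degrees."""
    poly = validate_polygon(poly)
    if poly.is_empty or poly.area == 0.0:
        return 0.0
    return spherical_area_mm2(poly, mm_per_degree=eye_radius_mm * DEG)


# ---------------------------------------------------------------------------
# Field layout

_CIRCLE_SEGMENTS = 16  # quad_segs -> 64-gon circles


@dataclass(frozen=True)
class Field:
    index: int
    center: RetinalPoint
    radius_deg: float


@dataclass(eq=False)
class FieldLayout:
    """The seven ETDRS standard fields for one eye.

    ``fields`` are seven equal-radius circles in the angular chart; the
    analysis region is their union.  For per-field accounting every point
    of the union is assigned to the field with the nearest center (ties to
    the lowest index), so the per-field regions partition the union.
    """

    fields: list[Field]
    laterality: str
    mm_per_degree: float = DEFAULT_MM_PER_DEGREE
    disc_center: RetinalPoint = field(default_factory=lambda: RetinalPoint(0.0, 0.0))
    fovea_center: RetinalPoint = field(default_factory=lambda: RetinalPoint(0.0, 0.0))

    @property
    def eye_radius_mm(self) -> float:
        return self.mm_per_degree / DEG

    @cached_property
    def circles(self) -> list[Polygon]:
        return [
            Point(f.center).buffer(f.radius_deg, quad_segs=_CIRCLE_SEGMENTS)
            for f in self.fields
        ]

    @cached_property
    def union(self) -> Polygon | MultiPolygon:
        return unary_union(self.circles)

    @cached_property
    def union_prepared(self):
        return prep(self.union)

    @cached_property
    def union_area_mm2(self) -> float:
        return spherical_area_mm2(self.union, self.mm_per_degree)

    @cached_property
    def assignment_cells(self) -> list[Polygon]:
        """Nearest-center dominance cell of each field, clipped to the union."""
        centers = np.array([f.center for f in self.fields], dtype=float)
        cells = []
        for i in range(len(centers)):
            cell = box(-720.0, -720.0, 720.0, 720.0)
            for j in range(len(centers)):
                if j == i:
                    continue
                n = centers[j] - centers[i]
                b = 0.5 * float(centers[j] @ centers[j] - centers[i] @ centers[i])
                cell = cell.intersection(_halfplane(n, b))
                if cell.is_empty:
                    break
            cells.append(cell.intersection(self.union))
        return cells

    @cached_property
    def cells_prepared(self):
        return [prep(c) for c in self.assignment_cells]

    @cached_property
    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        """(temporal_unit, superior_unit) chart vectors of this eye."""
        u = np.asarray(self.disc_center, dtype=float) - np.asarray(self.fovea_center, dtype=float)
        u = u / np.linalg.norm(u)  # nasal direction
        v = np.array([-u[1], u[0]])
        if v[1] < 0:
            v = -v
        return (-u, v)


def _halfplane(n: np.ndarray, b: float, extent: float = 4000.0) -> Polygon:
    """Chart polygon approximating the halfplane {p : p . n <= b}."""
    norm = float(np.hypot(n[0], n[1]))
    nh = n / norm
    p0 = nh * (b / norm)
    d = np.array([-nh[1], nh[0]])
    corners = [
        p0 + extent * d,
        p0 - extent * d,
        p0 - extent * d - extent * nh,
        p0 + extent * d - extent * nh,
    ]
    return Polygon(corners)


def build_field_layout(
    disc_center: RetinalPoint | Sequence[float],
    fovea_center: RetinalPoint | Sequence[float],
    laterality: str,
    field_radius_deg: float = DEFAULT_FIELD_RADIUS_DEG,
    mm_per_degree: float = DEFAULT_MM_PER_DEGREE,
    field_table: dict[int, tuple[str, float, float]] | None = None,
) -> FieldLayout:
    """Build the 7-circle layout from disc/fovea landmarks and laterality.

    The chart longitude runs along the disc–fovea axis with temporal
    positive for OD; OS layouts are the mirror image in longitude.  The
    disc must lie nasal to the fovea (longitude below the fovea's for OD,
    above for OS), otherwise a :class:`LandmarkError` is raised.
    """
    if laterality not in ("OD", "OS"):
        raise LandmarkError(f"laterality must be 'OD' or 'OS', got {laterality!r}")
    disc = RetinalPoint(*disc_center)
    fovea = RetinalPoint(*fovea_center)
    dx = disc.longitude - fovea.longitude
    dy = disc.latitude - fovea.latitude
    if math.hypot(dx, dy) < 1e-9:
        raise LandmarkError("disc and fovea landmarks coincide")
    if abs(dx) < 1e-9:
        raise LandmarkError("disc–fovea axis is vertical; landmarks implausible")
    if (laterality == "OD" and dx >= 0) or (laterality == "OS" and dx <= 0):
        raise LandmarkError(
            f"disc on the temporal side of the fovea is inconsistent with {laterality}"
        )

    u = np.array([dx, dy]) / math.hypot(dx, dy)  # nasal unit
    t_hat = -u  # temporal unit
    v_hat = np.array([-u[1], u[0]])
    if v_hat[1] < 0:
        v_hat = -v_hat  # superior unit

    anchors = {"disc": np.array(disc, dtype=float), "fovea": np.array(fovea, dtype=float)}
    table = field_table if field_table is not None else DEFAULT_FIELD_TABLE
    fields = []
    for idx in sorted(table):
        anchor_name, a_t, a_v = table[idx]
        c = anchors[anchor_name] + field_radius_deg * (a_t * t_hat + a_v * v_hat)
        fields.append(Field(index=idx, center=RetinalPoint(c[0], c[1]), radius_deg=field_radius_deg))
    return FieldLayout(
        fields=fields,
        laterality=laterality,
        mm_per_degree=mm_per_degree,
        disc_center=disc,
        fovea_center=fovea,
    )


# ---------------------------------------------------------------------------
# Fractional polygon-field overlap


@dataclass
class OverlapResult:
    """Partition of a lesion's area over the seven fields and the exterior.

    ``per_field_area`` are spherical mm^2 after nearest-center overlap
    disambiguation; fractions are shares of the lesion's total area, so
    per-field fractions plus the outside fraction sum to one.
    """

    per_field_area: np.ndarray  # (7,), mm^2
    outside_area: float
    per_field_fraction: np.ndarray  # (7,)
    outside_fraction: float
    total_area_mm2: float


def field_overlap(
    poly: Polygon | Sequence[Sequence[float]], layout: FieldLayout
) -> OverlapResult:
    """Split a lesion polygon's area over the seven fields (plus outside).

    Every point of the 7-circle union belongs to exactly one field (the
    nearest field center; ties go to the lowest field index), so the
    per-field areas partition the lesion's in-union area.  A zero-area
    polygon is reported as wholly outside.
    """
    poly = validate_polygon(poly)
    n = len(layout.fields)
    areas = np.zeros(n)
    if poly.is_empty or poly.area == 0.0:
        return OverlapResult(areas, 0.0, np.zeros(n), 1.0, 0.0)

    mpd = layout.mm_per_degree
    if layout.union_prepared.disjoint(poly):
        total = spherical_area_mm2(poly, mpd)
        return OverlapResult(areas, total, np.zeros(n), 1.0, total)

    # fast path: lesion wholly within one assignment cell
    for i, cell in enumerate(layout.cells_prepared):
        if cell.contains_properly(poly):
            total = spherical_area_mm2(poly, mpd)
            areas[i] = total
            frac = np.zeros(n)
            frac[i] = 1.0
            return OverlapResult(areas, 0.0, frac, 0.0, total)

    inside = poly.intersection(layout.union)
    outside_geom = poly.difference(layout.union)
    for i, cell in enumerate(layout.assignment_cells):
        piece = inside.intersection(cell)
        areas[i] = spherical_area_mm2(piece, mpd)
    outside_area = spherical_area_mm2(outside_geom, mpd)
    total = float(areas.sum() + outside_area)
    if total == 0.0:
        return OverlapResult(areas, outside_area, np.zeros(n), 1.0, 0.0)
    fractions = areas / total
    return OverlapResult(areas, outside_area, fractions, outside_area / total, total)


# ---------------------------------------------------------------------------
# Helpers for other modules


def quadrant_of(point: Sequence[float], layout: FieldLayout) -> str:
    """Fovea-centered anatomical quadrant of a chart point."""
    t_hat, v_hat = layout.axes
    rel = np.asarray(point, dtype=float) - np.asarray(layout.fovea_center, dtype=float)
    s = float(rel @ t_hat)
    h = float(rel @ v_hat)
    if h > 0:
        return "superotemporal" if s > 0 else "superonasal"
    return "inferotemporal" if s > 0 else "inferonasal"


QUADRANTS: tuple[str, ...] = (
    "superotemporal",
    "superonasal",
    "inferotemporal",
    "inferonasal",
)


def layout_to_geojson(layout: FieldLayout) -> dict:
    """Export the seven field circles as a GeoJSON FeatureCollection."""
    features = []
    for f, circle in zip(layout.fields, layout.circles):
        features.append(
            {
                "type": "Feature",
                "properties": {"field": f.index, "radius_deg": f.radius_deg},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[list(c) for c in circle.exterior.coords]],
                },
            }
        )
    return {
        "type": "FeatureCollection",
        "metadata": {"crs": "retinal-degrees", "laterality": layout.laterality},
        "features": features,
    }
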
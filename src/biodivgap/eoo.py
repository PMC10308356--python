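"""Extent-of-occurrence estimation.

EOO is the area of the minimum convex polygon (MCP) around a species'
occurrence records — the range metric used by IUCN Red List criterion B1.
Estimation proceeds in an equal-area projected plane:

1. project occurrence coordinates with a cylindrical equal-area projection
   (standard parallel 30 deg, the World-Behrmann convention, on the authalic
   sphere);
2. build the convex hull (Andrew monotone chain);
3. compute the raw hull area (shoelace) and a terrestrially masked area by
   rasterizing at a configurable resolution (default 1 km^2) and counting
   cells whose center falls inside both the hull and the country's land.

Species with fewer than three distinct points, or with all points collinear,
receive a status code instead of an area and are excluded from downstream
range-size summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union

if TYPE_CHECKING:  # pragma: no cover
    from .ingest import CountryMask, OccurrenceRecord
    from .thinning import GridSpec

#: IUCN criterion B1 area threshold for Vulnerable (km^2); the flag is
#: advisory — B1 listing also requires concurring threat conditions.
B1_VULNERABLE_KM2 = 20_000.0


@dataclass(frozen=True)
class ProjectionSpec:
    """Cylindrical equal-area projection on the authalic sphere.

    Forward map (lon, lat in degrees; x, y in km):

        x = R * lambda * cos(phi0)
        y = R * sin(phi) / cos(phi0)

    with ``phi0`` the standard parallel. At ``standard_parallel_deg = 30``
    this is the Behrmann convention. The map is exactly area-preserving on
    the sphere: a lon/lat rectangle of angular extent (d_lambda, d_sin_phi)
    projects to area R^2 * d_lambda * d_sin_phi.
    """

    standard_parallel_deg: float = 30.0
    sphere_radius_km: float = 6371.0088

    @property
    def cos_phi0(self) -> float:
        return math.cos(math.radians(self.standard_parallel_deg))


@dataclass(frozen=True)
class RangeEstimate:
    species_id: str
    source: str
    n_records_used: int
    hull_vertices: tuple[tuple[float, float], ...]  # projected km; empty if degenerate
    eoo_raw_km2: float | None
    eoo_masked_km2: float | None
    status: str  # ok | insufficient_points | degenerate


@dataclass(frozen=True)
class B1Flag:
    species_id: str
    source: str
    below_vulnerable_threshold: bool


def project(lon, lat, proj: ProjectionSpec = ProjectionSpec()):
    """Forward-project WGS84 degrees to equal-area km. Accepts scalars or arrays."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    R = proj.sphere_radius_km
    c = proj.cos_phi0
    x = R * np.radians(lon) * c
    y = R * np.sin(np.radians(lat)) / c
    if x.ndim == 0:
        return float(x), float(y)
    return x, y


def unproject(x, y, proj: ProjectionSpec = ProjectionSpec()):
    """Inverse of :func:`project`; x, y in km."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    R = proj.sphere_radius_km
    c = proj.cos_phi0
    lon = np.degrees(x / (R * c))
    lat = np.degrees(np.arcsin(np.clip(y * c / R, -1.0, 1.0)))
    if lon.ndim == 0:
        return float(lon), float(lat)
    return lon, lat


def project_geometry(geom, proj: ProjectionSpec = ProjectionSpec()):
    """Project a shapely geometry (lon/lat degrees) into equal-area km."""
    return shapely.transform(geom, lambda coords: np.column_stack(
        project(coords[:, 0], coords[:, 1], proj)))


def convex_hull(points: Iterable[Sequence[float]]) -> np.ndarray | None:
    """Andrew monotone-chain convex hull.

    Duplicate points are collapsed first. Returns the hull vertices in
    counter-clockwise order (no repeated closing vertex), or ``None`` when
    fewer than three distinct points remain or all points are collinear.
    Collinear boundary points are not hull vertices (strict-turn hull).
    """
    pts = sorted({(float(p[0]), float(p[1])) for p in points})
    if len(pts) < 3:
        return None

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    def half(seq):
        chain: list[tuple[float, float]] = []
        for p in seq:
            while len(chain) >= 2 and cross(chain[-2], chain[-1], p) <= 0:
                chain.pop()
            chain.append(p)
        return chain

    lower = half(pts)
    upper = half(reversed(pts))
    hull = lower[:-1] + upper[:-1]
    if len(hull) < 3:
        return None  # all collinear
    return np.asarray(hull, dtype=float)


def polygon_area(polygon) -> float:
    """Absolute shoelace area of a simple polygon (km^2 for km vertices).

    Orientation-independent. Raises ``ValueError`` for self-intersecting
    rings.
    """
    coords = np.asarray(polygon, dtype=float)
    if coords.shape[0] >= 2 and np.allclose(coords[0], coords[-1]):
        coords = coords[:-1]
    if coords.shape[0] < 3:
        raise ValueError("polygon needs at least 3 vertices")
    if not Polygon(coords).is_valid:
        raise ValueError("self-intersecting polygon")
    x, y = coords[:, 0], coords[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def _land_union_projected(country: "CountryMask", proj: ProjectionSpec):
    return unary_union([project_geometry(p, proj) for p in country.land_polygons])


def rasterize_and_mask(hull_vertices, land_projected, grid: "GridSpec") -> float:
    """Masked EOO: cell-center containment count times cell area.

    ``hull_vertices`` are projected km; ``land_projected`` is a shapely
    geometry in the same projected km space. A cell counts when its center
    lies inside (boundary inclusive) both the hull and the land. Iteration
    is restricted to the hull's bounding box of cells.
    """
    hull = Polygon(np.asarray(hull_vertices, dtype=float))
    cell_km = grid.cell_size_m / 1000.0
    ox_km, oy_km = grid.origin[0] / 1000.0, grid.origin[1] / 1000.0
    minx, miny, maxx, maxy = hull.bounds
    i0 = math.floor((minx - ox_km) / cell_km)
    i1 = math.floor((maxx - ox_km) / cell_km)
    j0 = math.floor((miny - oy_km) / cell_km)
    j1 = math.floor((maxy - oy_km) / cell_km)
    cx = ox_km + (np.arange(i0, i1 + 1) + 0.5) * cell_km
    cy = oy_km + (np.arange(j0, j1 + 1) + 0.5) * cell_km
    gx, gy = np.meshgrid(cx, cy)
    gx, gy = gx.ravel(), gy.ravel()
    in_hull = shapely.intersects_xy(hull, gx, gy)
    if not in_hull.any():
        return 0.0
    in_land = shapely.intersects_xy(land_projected, gx[in_hull], gy[in_hull])
    return float(in_land.sum()) * cell_km * cell_km


def estimate_eoo(
    records: Sequence["OccurrenceRecord"],
    country: "CountryMask",
    proj: ProjectionSpec = ProjectionSpec(),
    grid: "GridSpec | None" = None,
    land_projected=None,
) -> RangeEstimate:
    """Estimate EOO for the records of one (species, source) pair.

    Records are assumed cleaned and thinned. ``land_projected`` may be
    supplied to reuse a projected land union across many species.
    """
    from .thinning import GridSpec

    if grid is None:
        grid = GridSpec()
    species = {r.species_id for r in records}
    sources = {r.source for r in records}
    if len(species) != 1 or len(sources) != 1:
        raise ValueError("estimate_eoo expects records of exactly one species and source")
    species_id, source = species.pop(), sources.pop()

    lon = np.array([r.lon for r in records])
    lat = np.array([r.lat for r in records])
    x, y = project(lon, lat, proj)
    pts = np.column_stack([np.atleast_1d(x), np.atleast_1d(y)])
    n_distinct = len({(px, py) for px, py in pts})
    if n_distinct < 3:
        return RangeEstimate(species_id, source, len(records), (), None, None,
                             "insufficient_points")
    hull = convex_hull(pts)
    if hull is None:
        return RangeEstimate(species_id, source, len(records), (), None, None, "degenerate")
    raw = polygon_area(hull)
    if land_projected is None:
        land_projected = _land_union_projected(country, proj)
    masked = rasterize_and_mask(hull, land_projected, grid)
    return RangeEstimate(species_id, source, len(records),
                         tuple(map(tuple, hull)), raw, masked, "ok")


def classify_b1(eoo_masked_km2: float, species_id: str = "", source: str = "") -> B1Flag:
    """Flag whether a masked EOO falls below the criterion-B1 Vulnerable area.

    Strict inequality: exactly 20,000 km^2 is not below the threshold.
    """
    if eoo_masked_km2 < 0:
        raise ValueError("area must be nonnegative")
    return B1Flag(species_id, source, eoo_masked_km2 < B1_VULNERABLE_KM2)
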
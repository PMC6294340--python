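"""Adaptive locale construction from residential coordinates.

Locales are contiguous map units built in three stages: (1) subject
coordinates, already blurred to a privacy grid, are collapsed to unique
generator points with multiplicities; (2) the plane is partitioned by the
Voronoi tessellation of the generators, with neighbour relations given by
the dual Delaunay triangulation; (3) neighbouring cells are merged,
smallest first, until every locale holds at least ``n_min`` subjects.
Because cell size adapts to the point density, locale area is inversely
proportional to population density, which is why the locale map doubles as
a population-density instrument.

All coordinates are planar metres (projected); geographic lon/lat must be
projected upstream.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import unary_union, voronoi_diagram

logger = logging.getLogger(__name__)

__all__ = [
    "GridPoint",
    "Tessellation",
    "Locale",
    "LocaleMap",
    "collapse_to_grid",
    "build_tessellation",
    "grow_locales",
    "assign_subjects",
    "locale_map_to_geojson",
]


@dataclass(frozen=True)
class GridPoint:
    """One occupied grid cell, identified by its lower-left corner."""

    x: float
    y: float
    multiplicity: int = 1


@dataclass
class Tessellation:
    """Voronoi cells over generator points with Delaunay adjacency.

    ``cells`` may be ``None`` for synthetic tessellations used to drive the
    merge algorithm directly (e.g. a hand-built neighbour graph); polygon
    dependent outputs are then unavailable.
    """

    generators: list[GridPoint]
    neighbor_graph: dict[int, set[int]]
    cells: list[Polygon] | None = None
    boundary: Polygon | None = None

    @property
    def n_generators(self) -> int:
        return len(self.generators)


@dataclass
class Locale:
    id: int
    member_generator_ids: set[int]
    n_members: int
    centroid: tuple[float, float]
    polygon: Polygon | None = None
    area_km2: float | None = None

    @property
    def population_density(self) -> float | None:
        """Persons per km² (None when polygons were not built)."""
        if self.area_km2 is None or self.area_km2 <= 0:
            return None
        return self.n_members / self.area_km2


@dataclass
class LocaleMap:
    locales: list[Locale]
    assignment: dict[int, int]  # generator_id -> locale_id
    locale_neighbors: dict[int, set[int]]
    tessellation: Tessellation
    n_min: int

    def locale_by_id(self, locale_id: int) -> Locale:
        return self._index[locale_id]

    def __post_init__(self) -> None:
        self._index = {loc.id: loc for loc in self.locales}

    # -- lookup -----------------------------------------------------------
    def assign_points(self, xy: np.ndarray) -> np.ndarray:
        """Locale id for each row of an (n, 2) coordinate array.

        Points are assigned to the locale of their nearest generator, which
        coincides with polygon containment for interior points and resolves
        exact boundary ties deterministically (lowest generator index).
        Points outside the boundary polygon are assigned to the nearest
        locale with a logged warning.
        """
        xy = np.asarray(xy, dtype=float)
        coords = np.array([[g.x, g.y] for g in self.tessellation.generators])
        tree = cKDTree(coords)
        _, gen_idx = tree.query(xy)
        if self.tessellation.boundary is not None:
            inside = shapely.contains(
                self.tessellation.boundary, shapely.points(xy[:, 0], xy[:, 1])
            )
            n_out = int((~inside).sum())
            if n_out:
                logger.warning(
                    "%d point(s) outside the boundary polygon; assigned to the nearest locale",
                    n_out,
                )
        return np.array([self.assignment[int(i)] for i in gen_idx])


def collapse_to_grid(
    subjects: pd.DataFrame,
    resolution: float = 1000.0,
    x_col: str = "x_birth",
    y_col: str = "y_birth",
) -> list[GridPoint]:
    """Collapse subject coordinates to unique grid cells with multiplicities.

    Binning is half-open: cell indices are ``floor(x / resolution)`` and the
    cell is identified by its lower-left corner. The sum of multiplicities
    equals the number of subjects.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    x = subjects[x_col].to_numpy(dtype=float)
    y = subjects[y_col].to_numpy(dtype=float)
    bad = ~(np.isfinite(x) & np.isfinite(y))
    if bad.any():
        rows = subjects.index[bad].tolist()
        raise ValueError(f"non-finite coordinates in rows {rows[:10]}")
    ix = np.floor(x / resolution).astype(np.int64)
    iy = np.floor(y / resolution).astype(np.int64)
    cells, counts = np.unique(np.column_stack([ix, iy]), axis=0, return_counts=True)
    return [
        GridPoint(float(cx * resolution), float(cy * resolution), int(m))
        for (cx, cy), m in zip(cells, counts)
    ]


def _incircle_det(a, b, c, d) -> float:
    """Signed in-circle determinant of d against the circle through a, b, c."""
    m = np.array(
        [
            [a[0] - d[0], a[1] - d[1], (a[0] - d[0]) ** 2 + (a[1] - d[1]) ** 2],
            [b[0] - d[0], b[1] - d[1], (b[0] - d[0]) ** 2 + (b[1] - d[1]) ** 2],
            [c[0] - d[0], c[1] - d[1], (c[0] - d[0]) ** 2 + (c[1] - d[1]) ** 2],
        ]
    )
    return float(np.linalg.det(m))


def _canonical_diagonal(coords, a, b, c, d) -> tuple[int, int]:
    """Pick the diagonal of a co-circular quad {a,b} vs {c,d}.

    Rule: order each diagonal's endpoints lexicographically by (x, y); the
    diagonal whose lower endpoint sorts first wins, ties broken by the
    upper endpoints. This is the documented deterministic tie-break for
    Delaunay degeneracies (four or more co-circular points).
    """

    def key(i, j):
        pi, pj = tuple(coords[i]), tuple(coords[j])
        lo, hi = (pi, pj) if pi <= pj else (pj, pi)
        return (lo, hi)

    return (a, b) if key(a, b) <= key(c, d) else (c, d)


def build_tessellation(
    points: list[GridPoint],
    boundary: Polygon | None = None,
    buffer_resolution: float = 1000.0,
) -> Tessellation:
    """Voronoi cells clipped to a boundary, plus the Delaunay neighbour graph.

    The default boundary is the convex hull of the generators buffered by one
    grid resolution, so every cell has finite area. Co-circular quadruples
    (where the Delaunay triangulation is not unique) are resolved by a
    lexicographic diagonal rule; the affected Voronoi cells meet at a single
    point and the chosen diagonal's endpoints are declared neighbours.
    """
    coords = np.array([[p.x, p.y] for p in points], dtype=float)
    if len(points) < 3:
        raise ValueError("tessellation requires at least 3 generators")
    if len(np.unique(coords, axis=0)) != len(coords):
        raise ValueError("generator coordinates must be unique (collapse first)")
    if _all_collinear(coords):
        raise ValueError("generators are collinear; Voronoi tessellation is degenerate")

    if boundary is None:
        boundary = MultiPoint([tuple(c) for c in coords]).convex_hull.buffer(
            buffer_resolution
        )
    if not all(boundary.covers(Point(*c)) for c in coords):
        raise ValueError("boundary polygon must contain all generators")

    # Voronoi polygons via GEOS; match each polygon back to its generator.
    raw = voronoi_diagram(
        MultiPoint([tuple(c) for c in coords]), envelope=boundary.buffer(1.0)
    )
    cells: list[Polygon | None] = [None] * len(points)
    tree = shapely.STRtree(list(raw.geoms))
    gen_pts = shapely.points(coords[:, 0], coords[:, 1])
    for i, gp in enumerate(gen_pts):
        hits = tree.query(gp, predicate="intersects")
        if len(hits) == 0:  # pragma: no cover - GEOS always covers generators
            raise RuntimeError(f"generator {i} not covered by any Voronoi cell")
        cells[i] = raw.geoms[int(hits[0])].intersection(boundary)

    # Delaunay adjacency with deterministic co-circular tie-break.
    tri = Delaunay(coords)
    neighbor_graph: dict[int, set[int]] = {i: set() for i in range(len(points))}
    edge_tris: dict[tuple[int, int], list[int]] = {}
    for s in tri.simplices:
        for i in range(3):
            e = tuple(sorted((int(s[i]), int(s[(i + 1) % 3]))))
            edge_tris.setdefault(e, []).append(int(s[(i + 2) % 3]))
    scale = float(np.ptp(coords)) or 1.0
    edges = set(edge_tris)
    for (a, b), opp in sorted(edge_tris.items()):
        if len(opp) != 2:
            continue
        c, d = sorted(opp)
        det = _incircle_det(coords[a], coords[b], coords[c], coords[d])
        if abs(det) <= 1e-9 * scale**4:
            keep = _canonical_diagonal(coords, a, b, c, d)
            if keep != (a, b) and tuple(sorted(keep)) != (a, b):
                edges.discard((a, b))
                edges.add(tuple(sorted(keep)))
    for a, b in edges:
        neighbor_graph[a].add(b)
        neighbor_graph[b].add(a)

    return Tessellation(
        generators=list(points),
        neighbor_graph=neighbor_graph,
        cells=cells,
        boundary=boundary,
    )


def _all_collinear(coords: np.ndarray) -> bool:
    if len(coords) < 3:
        return True
    p0 = coords[0]
    d = coords - p0
    cross = d[:, 0] * d[1, 1] - d[:, 1] * d[1, 0]
    # use the first point not identical to p0 as direction
    for k in range(1, len(coords)):
        if np.any(coords[k] != p0):
            d1 = coords[k] - p0
            cross = d[:, 0] * d1[1] - d[:, 1] * d1[0]
            break
    scale = max(float(np.ptp(coords)), 1.0)
    return bool(np.all(np.abs(cross) < 1e-9 * scale**2))


@dataclass
class _ProtoLocale:
    id: int
    gens: set[int]
    n: int
    wx: float  # population-weighted coordinate sums
    wy: float
    neighbors: set[int] = field(default_factory=set)

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.wx / self.n, self.wy / self.n)


def grow_locales(tess: Tessellation, n_min: int = 100) -> LocaleMap:
    """Merge Voronoi cells into locales of at least ``n_min`` members.

    Merge schedule (deterministic): repeatedly take the locale with the
    fewest members below ``n_min`` (ties: lower id) and merge it into the
    neighbouring locale whose population-weighted centroid is nearest
    (ties: fewer graph neighbours, then lower id); the merged locale keeps
    the lower id. A connected component whose total population is below
    ``n_min`` becomes a single locale with a warning.
    """
    if n_min < 1:
        raise ValueError("n_min must be >= 1")
    gens = tess.generators
    locales: dict[int, _ProtoLocale] = {}
    for i, g in enumerate(gens):
        locales[i] = _ProtoLocale(
            id=i, gens={i}, n=g.multiplicity, wx=g.x * g.multiplicity,
            wy=g.y * g.multiplicity, neighbors=set(tess.neighbor_graph[i]),
        )

    total = sum(g.multiplicity for g in gens)
    if total < n_min:
        warnings.warn(
            f"total population {total} below n_min={n_min}; returning a single locale",
            stacklevel=2,
        )

    finalized_small: set[int] = set()  # exhausted components below n_min
    while True:
        pending = [
            loc for loc in locales.values()
            if loc.n < n_min and loc.id not in finalized_small
        ]
        if not pending:
            break
        loc = min(pending, key=lambda L: (L.n, L.id))
        if not loc.neighbors:
            if loc.gens != set(range(len(gens))):
                warnings.warn(
                    f"connected component containing generator {min(loc.gens)} has "
                    f"only {loc.n} members (< n_min={n_min}); kept as one locale",
                    stacklevel=2,
                )
            finalized_small.add(loc.id)
            continue
        cx, cy = loc.centroid
        target = min(
            (locales[j] for j in loc.neighbors),
            key=lambda L: (
                math.hypot(L.centroid[0] - cx, L.centroid[1] - cy),
                len(L.neighbors),
                L.id,
            ),
        )
        keep, drop = (loc, target) if loc.id < target.id else (target, loc)
        keep.gens |= drop.gens
        keep.n += drop.n
        keep.wx += drop.wx
        keep.wy += drop.wy
        new_nb = (keep.neighbors | drop.neighbors) - {keep.id, drop.id}
        keep.neighbors = new_nb
        for j in new_nb:
            locales[j].neighbors.discard(drop.id)
            locales[j].neighbors.add(keep.id)
        finalized_small.discard(drop.id)
        del locales[drop.id]

    # Re-label locales 0..k-1 in order of their minimum generator id.
    ordered = sorted(locales.values(), key=lambda L: min(L.gens))
    old_to_new = {L.id: k for k, L in enumerate(ordered)}
    out: list[Locale] = []
    assignment: dict[int, int] = {}
    for k, L in enumerate(ordered):
        poly = area = None
        if tess.cells is not None:
            poly = unary_union([tess.cells[g] for g in L.gens])
            area = poly.area / 1e6
        out.append(
            Locale(
                id=k, member_generator_ids=set(L.gens), n_members=L.n,
                centroid=L.centroid, polygon=poly, area_km2=area,
            )
        )
        for g in L.gens:
            assignment[g] = k
    locale_neighbors: dict[int, set[int]] = {k: set() for k in range(len(ordered))}
    for L in ordered:
        locale_neighbors[old_to_new[L.id]] = {old_to_new[j] for j in L.neighbors}
    return LocaleMap(
        locales=out, assignment=assignment, locale_neighbors=locale_neighbors,
        tessellation=tess, n_min=n_min,
    )


def assign_subjects(
    locale_map: LocaleMap,
    subjects: pd.DataFrame,
    which_age: str = "birth",
) -> pd.Series:
    """Locale id for every subject at the chosen age ('birth', 'age5', 'age7').

    Cases whose coordinates were excluded from map construction still
    receive an assignment (nearest-generator rule is total).
    """
    if which_age not in ("birth", "age5", "age7"):
        raise ValueError("which_age must be one of 'birth', 'age5', 'age7'")
    xy = subjects[[f"x_{which_age}", f"y_{which_age}"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        bad = subjects.index[~np.isfinite(xy).all(axis=1)].tolist()
        raise ValueError(f"non-finite coordinates in rows {bad[:10]}")
    return pd.Series(locale_map.assign_points(xy), index=subjects.index, name="locale_id")


def locale_map_to_geojson(
    locale_map: LocaleMap, extra_properties: dict[int, dict] | None = None
) -> dict:
    """LocaleMap as a GeoJSON FeatureCollection (planar CRS noted in metadata)."""
    feats = []
    for loc in locale_map.locales:
        props = {
            "locale_id": loc.id,
            "n_members": loc.n_members,
            "area_km2": loc.area_km2,
            "density": loc.population_density,
        }
        if extra_properties and loc.id in extra_properties:
            props.update(extra_properties[loc.id])
        geom = shapely.geometry.mapping(loc.polygon) if loc.polygon is not None else None
        feats.append({"type": "Feature", "geometry": geom, "properties": props})
    return {
        "type": "FeatureCollection",
        "features": feats,
        "metadata": {
            "crs_note": "planar projected coordinates in metres (not WGS84 lon/lat)",
            "n_min": locale_map.n_min,
        },
    }
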
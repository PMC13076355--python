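"""Planar geometric primitives used throughout the package.

All coordinates are planar meters in a single projected coordinate system;
geographic (lat/lon) input is not supported and must be projected upstream.

Paths (polylines) are ``(n, 2)`` float arrays.  Polygons are shapely
geometries.  Feature-crossing counts use a strict transversal-intersection
test: tangential touches and collinear overlaps do not count as crossings,
and a point lying exactly on a polygon boundary counts as inside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import (
    LineString,
    MultiPoint,
    MultiPolygon,
    Polygon,
    mapping,
    shape,
)
from shapely.ops import unary_union

from .errors import (
    DegenerateInputError,
    InvalidGeometryError,
    UnsupportedOperationError,
)

__all__ = [
    "Landscape",
    "as_path",
    "buffer_polygon",
    "count_crossings",
    "count_crossings_segments",
    "count_points_in_polygon",
    "minimum_convex_polygon",
    "points_in_polygon_mask",
    "read_landscape",
    "rotate_path",
    "segments_of",
    "translate_path",
    "union_polygons",
    "write_landscape",
]

# Quarter-circle resolution for buffer arcs; area tests use a 1% tolerance.
BUFFER_QUAD_SEGS = 16


def as_path(vertices, min_vertices: int = 2) -> np.ndarray:
    """Validate and return a polyline as an ``(n, 2)`` float array."""
    arr = np.asarray(vertices, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidGeometryError(f"expected an (n, 2) vertex array, got shape {arr.shape}")
    if arr.shape[0] < min_vertices:
        raise InvalidGeometryError(f"path needs at least {min_vertices} vertices, got {arr.shape[0]}")
    if not np.all(np.isfinite(arr)):
        raise InvalidGeometryError("non-finite coordinates in path")
    return arr


def segments_of(polylines) -> np.ndarray:
    """Concatenate polylines into an ``(m, 2, 2)`` array of segments."""
    segs = []
    for line in polylines:
        arr = as_path(line)
        segs.append(np.stack([arr[:-1], arr[1:]], axis=1))
    if not segs:
        return np.empty((0, 2, 2))
    return np.concatenate(segs, axis=0)


def _cross(ux, uy, vx, vy):
    return ux * vy - uy * vx


def count_crossings_segments(paths: np.ndarray, segs: np.ndarray, chunk: int = 128) -> np.ndarray:
    """Transversal crossing counts for a batch of equal-length paths.

    Parameters
    ----------
    paths : (k, n, 2) array of path vertices.
    segs : (m, 2, 2) array of feature segments.

    Returns
    -------
    (k,) int array of crossing counts.  Only proper (interior-interior)
    intersections count; endpoint tangency and collinear overlap contribute 0,
    as do zero-length path segments.
    """
    paths = np.asarray(paths, dtype=float)
    if paths.ndim == 2:
        paths = paths[None]
    if not np.all(np.isfinite(paths)):
        raise InvalidGeometryError("non-finite coordinates in path batch")
    k, n, _ = paths.shape
    if n < 2 or segs.shape[0] == 0:
        return np.zeros(k, dtype=int)
    q0 = segs[:, 0]  # (m, 2)
    q1 = segs[:, 1]
    dq = q1 - q0
    out = np.zeros(k, dtype=int)
    for lo in range(0, k, chunk):
        p = paths[lo : lo + chunk]
        p0 = p[:, :-1][:, :, None, :]  # (c, a, 1, 2)
        p1 = p[:, 1:][:, :, None, :]
        dp = p1 - p0
        # orientation of feature endpoints relative to each path segment
        d1 = _cross(dp[..., 0], dp[..., 1], q0[..., 0] - p0[..., 0], q0[..., 1] - p0[..., 1])
        d2 = _cross(dp[..., 0], dp[..., 1], q1[..., 0] - p0[..., 0], q1[..., 1] - p0[..., 1])
        # orientation of path endpoints relative to each feature segment
        d3 = _cross(dq[..., 0], dq[..., 1], p0[..., 0] - q0[..., 0], p0[..., 1] - q0[..., 1])
        d4 = _cross(dq[..., 0], dq[..., 1], p1[..., 0] - q0[..., 0], p1[..., 1] - q0[..., 1])
        proper = (d1 * d2 < 0) & (d3 * d4 < 0)
        out[lo : lo + chunk] = proper.sum(axis=(1, 2))
    return out


def count_crossings(path, features) -> int:
    """Number of transversal intersections between ``path`` and line features.

    ``features`` is an iterable of polylines.  A path segment intersecting k
    distinct feature segments at k distinct interior points contributes k.
    """
    arr = as_path(path)
    segs = segments_of(features)
    return int(count_crossings_segments(arr[None], segs)[0])


def _require_valid_polygon(poly, *, positive_area: bool = True):
    if poly is None or poly.is_empty:
        raise InvalidGeometryError("empty polygon")
    if not poly.is_valid:
        raise InvalidGeometryError("invalid polygon (self-intersection or bad rings)")
    if positive_area and poly.area <= 0:
        raise InvalidGeometryError("polygon has zero area")


def points_in_polygon_mask(points, poly) -> np.ndarray:
    """Boolean mask of points inside or on the boundary of ``poly``."""
    _require_valid_polygon(poly)
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if not np.all(np.isfinite(pts)):
        raise InvalidGeometryError("non-finite coordinates in point set")
    return shapely.intersects_xy(poly, pts[:, 0], pts[:, 1])


def count_points_in_polygon(points, poly) -> int:
    """Number of points inside ``poly``; boundary points count as inside."""
    return int(points_in_polygon_mask(points, poly).sum())


def minimum_convex_polygon(points) -> Polygon:
    """100% minimum convex polygon (convex hull) of a point set."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 3:
        raise DegenerateInputError("convex polygon needs at least 3 points")
    if not np.all(np.isfinite(pts)):
        raise InvalidGeometryError("non-finite coordinates in point set")
    hull = MultiPoint(pts).convex_hull
    if not isinstance(hull, Polygon):
        raise DegenerateInputError("points are collinear; convex hull is degenerate")
    return hull


def union_polygons(a, b):
    """Union of two polygons (may be multi-part)."""
    _require_valid_polygon(a)
    _require_valid_polygon(b)
    return a.union(b)


def buffer_polygon(poly, distance: float, quad_segs: int = BUFFER_QUAD_SEGS):
    """Minkowski dilation of ``poly`` by ``distance`` meters."""
    _require_valid_polygon(poly)
    if distance < 0:
        raise UnsupportedOperationError("negative buffer distances are not supported")
    if distance == 0:
        return poly
    return poly.buffer(distance, quad_segs=quad_segs)


def rotate_path(path, angle: float, pivot) -> np.ndarray:
    """Rigid rotation of a path about ``pivot`` by ``angle`` radians."""
    arr = as_path(path, min_vertices=1)
    piv = np.asarray(pivot, dtype=float)
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return (arr - piv) @ rot.T + piv


def rotate_paths(path, angles, pivot) -> np.ndarray:
    """Batch of rigid rotations of one path: returns ``(len(angles), n, 2)``."""
    arr = as_path(path, min_vertices=1)
    piv = np.asarray(pivot, dtype=float)
    ang = np.asarray(angles, dtype=float)
    c, s = np.cos(ang), np.sin(ang)
    rel = arr - piv  # (n, 2)
    x = rel[:, 0][None, :] * c[:, None] - rel[:, 1][None, :] * s[:, None]
    y = rel[:, 0][None, :] * s[:, None] + rel[:, 1][None, :] * c[:, None]
    return np.stack([x, y], axis=-1) + piv


def translate_path(path, new_start) -> np.ndarray:
    """Shift a path so its first vertex lands on ``new_start``."""
    arr = as_path(path, min_vertices=1)
    shift = np.asarray(new_start, dtype=float) - arr[0]
    return arr + shift


@dataclass
class Landscape:
    """Named feature layers sharing one planar coordinate system (meters).

    ``roads`` and ``trails`` are lists of polylines; ``powerline`` is a list
    of polygons; ``road_buffer`` is the 5 m dilation of the road footprint;
    ``study_area`` bounds random starting points.
    """

    roads: list
    trails: list
    powerline: list
    road_buffer: object
    study_area: object
    road_polygon: object = None
    _road_segs: np.ndarray = field(default=None, repr=False, compare=False)
    _trail_segs: np.ndarray = field(default=None, repr=False, compare=False)
    _powerline_union: object = field(default=None, repr=False, compare=False)

    @property
    def road_segments(self) -> np.ndarray:
        if self._road_segs is None:
            self._road_segs = segments_of(self.roads)
        return self._road_segs

    @property
    def trail_segments(self) -> np.ndarray:
        if self._trail_segs is None:
            self._trail_segs = segments_of(self.trails)
        return self._trail_segs

    @property
    def powerline_union(self):
        if self._powerline_union is None:
            self._powerline_union = unary_union(self.powerline)
        return self._powerline_union


_LINE_LAYERS = {"roads", "trails"}
_POLY_LAYERS = {"powerline", "road_polygon", "boundary", "road_buffer"}


def read_landscape(path) -> Landscape:
    """Read feature layers from a GeoJSON FeatureCollection.

    Each feature must carry a ``layer`` property with one of the roles
    roads | trails | powerline | road_polygon | road_buffer | boundary.
    The ``boundary`` layer becomes the study area.
    """
    with open(path) as fh:
        gj = json.load(fh)
    layers: dict[str, list] = {}
    for feat in gj.get("features", []):
        role = feat.get("properties", {}).get("layer")
        if role is None:
            raise InvalidGeometryError("GeoJSON feature missing 'layer' property")
        geom = shape(feat["geometry"])
        layers.setdefault(role, []).append(geom)

    def lines(role):
        out = []
        for g in layers.get(role, []):
            if g.geom_type == "LineString":
                out.append(np.asarray(g.coords, dtype=float))
            elif g.geom_type == "MultiLineString":
                out.extend(np.asarray(part.coords, dtype=float) for part in g.geoms)
            else:
                raise InvalidGeometryError(f"layer {role!r} expects line geometry, got {g.geom_type}")
        return out

    def polys(role):
        out = []
        for g in layers.get(role, []):
            if g.geom_type == "Polygon":
                out.append(g)
            elif g.geom_type == "MultiPolygon":
                out.extend(g.geoms)
            else:
                raise InvalidGeometryError(f"layer {role!r} expects polygon geometry, got {g.geom_type}")
        return out

    boundary = polys("boundary")
    if not boundary:
        raise InvalidGeometryError("no 'boundary' layer in landscape file")
    buffers = polys("road_buffer")
    road_poly = polys("road_polygon")
    return Landscape(
        roads=lines("roads"),
        trails=lines("trails"),
        powerline=polys("powerline"),
        road_buffer=unary_union(buffers) if buffers else None,
        study_area=unary_union(boundary),
        road_polygon=unary_union(road_poly) if road_poly else None,
    )


def write_landscape(landscape: Landscape, path) -> None:
    """Write a landscape back out as a GeoJSON FeatureCollection."""
    feats = []

    def add(geom, role):
        if geom is None:
            return
        feats.append(
            {"type": "Feature", "properties": {"layer": role}, "geometry": mapping(geom)}
        )

    for line in landscape.roads:
        add(LineString(line), "roads")
    for line in landscape.trails:
        add(LineString(line), "trails")
    for poly in landscape.powerline:
        add(poly, "powerline")
    add(landscape.road_polygon, "road_polygon")
    add(landscape.road_buffer, "road_buffer")
    add(landscape.study_area, "boundary")
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
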
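"""α-shapes, epidermis modelling and cell-to-structure distances.

The α-shape of a 2D point set generalizes the convex hull: after Delaunay
triangulation, only simplices whose circumradius is at most 1/α are kept
(a circle of radius 1/α "rolled" around the points erases the rest), and
the kept triangles are dissolved into one or more boundary polygons.
α = 0 keeps every simplex and returns the convex hull; larger α gives
tighter, possibly disconnected shapes.  α is in 1/μm since coordinates
are in μm.

All geometry operates in the x-y projection: cell records are 3D, but
structures are modelled and distances measured in the section plane.
Distances go to the α-shape *contour vertices* held in a k-d tree — the
contour sampling density bounds the error against true edge distance —
and cells inside or on the shape are at distance 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import ConvexHull, Delaunay, cKDTree
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .io import CellTable, EpidermisContour, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PolygonSet:
    """Disjoint simple polygons (with possible holes), μm, x-y plane."""

    polygons: list[Polygon]
    alpha: float = 0.0

    @property
    def total_area(self) -> float:
        return float(sum(p.area for p in self.polygons))

    @property
    def is_empty(self) -> bool:
        return not self.polygons

    def covers_points(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask: point inside or on the boundary of any polygon."""
        xy = np.asarray(xy, dtype=float)
        pts = shapely.points(xy)
        mask = np.zeros(len(xy), dtype=bool)
        for poly in self.polygons:
            mask |= shapely.covers(poly, pts)
        return mask

    def boundary_vertices(self) -> np.ndarray:
        """All boundary (contour) vertices, exterior and hole rings."""
        chunks = []
        for poly in self.polygons:
            chunks.append(np.asarray(poly.exterior.coords)[:-1])
            for ring in poly.interiors:
                chunks.append(np.asarray(ring.coords)[:-1])
        return np.vstack(chunks) if chunks else np.empty((0, 2))

    def to_wkt(self) -> str:
        if not self.polygons:
            return "GEOMETRYCOLLECTION EMPTY"
        return shapely.MultiPolygon(self.polygons).wkt


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a = points[simplices[:, 0]]
    b = points[simplices[:, 1]]
    c = points[simplices[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    double_area = np.abs((b - a)[:, 0] * (c - a)[:, 1] - (b - a)[:, 1] * (c - a)[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        r = la * lb * lc / (2.0 * double_area)
    r[double_area == 0] = np.inf  # degenerate sliver: never kept for alpha > 0
    return r


def alpha_shape(points: np.ndarray, alpha: float) -> PolygonSet:
    """Compute the α-shape of a 2D point set.

    Parameters
    ----------
    points : (n, 2) array
        Point coordinates in μm.  Duplicates are removed (logged).
    alpha : float
        α parameter in 1/μm; simplices with circumradius ≤ 1/α are kept.
        ``alpha=0`` keeps everything and returns the convex hull.

    Returns
    -------
    PolygonSet
        Possibly empty (fewer than 3 distinct points, collinear input,
        or no simplex surviving the circumradius filter).
    """
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValidationError("points must be an (n, 2) array")
    unique = np.unique(points, axis=0)
    if len(unique) < len(points):
        logger.info("alpha_shape: removed %d duplicate point(s)",
                    len(points) - len(unique))
    if len(unique) < 3:
        logger.warning("alpha_shape: fewer than 3 distinct points; empty shape")
        return PolygonSet([], alpha)
    try:
        tri = Delaunay(unique)
    except Exception:  # qhull raises on exactly collinear input
        logger.warning("alpha_shape: degenerate (collinear) input; empty shape")
        return PolygonSet([], alpha)
    if tri.simplices.size == 0:
        return PolygonSet([], alpha)

    radii = _circumradii(unique, tri.simplices)
    keep = tri.simplices if alpha == 0 else tri.simplices[radii <= 1.0 / alpha]
    if len(keep) == 0:
        return PolygonSet([], alpha)
    union = unary_union([Polygon(unique[s]) for s in keep])
    if union.is_empty:
        return PolygonSet([], alpha)
    parts = list(union.geoms) if union.geom_type == "MultiPolygon" else [union]
    parts.sort(key=lambda p: p.bounds)  # deterministic component order
    return PolygonSet(parts, alpha)


def convex_hull_area(points: np.ndarray) -> float:
    """Area of the convex hull (independent reference for α = 0)."""
    return float(ConvexHull(np.asarray(points, dtype=float)).volume)


@dataclass
class EpidermisModel:
    """Epidermis α-shape plus a nearest-contour-vertex spatial index."""

    shape: PolygonSet
    contour_vertices: np.ndarray
    _tree: cKDTree

    def query(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest contour vertex for each 2D point: (distances, indices)."""
        d, i = self._tree.query(np.atleast_2d(np.asarray(xy, dtype=float)))
        return d, i


def build_epidermis_model(contour: EpidermisContour, alpha: float = 0.4) -> EpidermisModel:
    """Model the epidermis as the α-shape of its surface points.

    Surface points are projected to x-y, the α-shape computed, and the
    shape's boundary vertices loaded into a k-d tree for nearest-vertex
    queries.  Raises if the projection is too degenerate to form a shape.
    """
    xy = contour.vertices[:, :2]
    shape = alpha_shape(xy, alpha)
    if shape.is_empty:
        raise ValidationError("degenerate epidermis projection: no alpha-shape")
    vertices = shape.boundary_vertices()
    return EpidermisModel(shape, vertices, cKDTree(vertices))


@dataclass
class DistanceTable:
    """Per-cell distance r (μm) to a structure; r = 0 inside or on it."""

    distances: pd.DataFrame  # cell_id, distance_um, inside_epidermis


def distance_to_structure(table: CellTable, model: EpidermisModel) -> DistanceTable:
    """Distance of every cell to the epidermis model in the x-y plane.

    Cells covered by the α-shape (inside or on its boundary) are at
    r = 0; all others get the distance to the nearest contour vertex.
    """
    xy = table.positions("xy")
    inside = model.shape.covers_points(xy)
    dist, _ = model.query(xy)
    dist = np.where(inside, 0.0, dist)
    df = pd.DataFrame({
        "cell_id": table.cells["cell_id"].to_numpy(),
        "distance_um": dist,
        "inside_epidermis": inside,
    })
    return DistanceTable(df)
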
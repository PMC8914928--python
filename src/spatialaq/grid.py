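"""Hexagonal areal units: projection, tessellation and point aggregation.

Point-referenced sensor observations are projected into a kilometre-true
planar frame, overlaid with a regular hexagonal tessellation at a chosen
side length (the candidate spatial granularity), and aggregated per cell.
Hexagons are preferred over squares because they reduce visual field bias
and give a single, unambiguous first-order contiguity (edge sharing and
vertex sharing coincide).

The hexagon lattice is the Voronoi diagram of its centre lattice, so point
assignment is nearest-centre; boundary ties are broken toward the cell whose
centre is lexicographically smallest in (x, y), which keeps the assignment a
deterministic partition.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Polygon, mapping

from .errors import EmptyLayerError, InvalidCoordinateError

# WGS84 equatorial radius; the equirectangular frame below is kilometre-true
# in latitude and in longitude at the projection origin's parallel.
EARTH_RADIUS_KM = 6378.137

Statistic = Literal["mean", "median", "max"]


@dataclass
class PointDataset:
    """Point-referenced observations with one value per point.

    ``crs_tag`` is either ``"geographic-lonlat"`` (x = longitude, y =
    latitude, degrees) or ``"planar-km"``.  ``proj_origin`` records the
    equirectangular origin (lon0, lat0) once projected, enabling the exact
    inverse.  ``site`` and ``date`` are optional per-point metadata carried
    through from file readers.
    """

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    crs_tag: str = "planar-km"
    proj_origin: tuple[float, float] | None = None
    site: np.ndarray | None = None
    date: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.values)):
            raise ValueError("x, y and values must have equal length")
        if len(self.x) < 1:
            raise ValueError("a PointDataset needs at least one point")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("all values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def bbox(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the point cloud."""
        return (
            float(self.x.min()),
            float(self.y.min()),
            float(self.x.max()),
            float(self.y.max()),
        )


def project_to_planar(
    data: PointDataset,
    origin: tuple[float, float] | None = None,
    method: str = "equirectangular",
) -> PointDataset:
    """Project lon/lat points to a planar kilometre frame.

    The default (and only) method is the equirectangular projection about
    ``origin`` (lon0, lat0), defaulting to the data centroid:

        x = R * cos(lat0) * (lon - lon0) * pi/180
        y = R * (lat - lat0) * pi/180

    Adequate at desk scale; cell areas in the resulting frame are
    approximate away from the origin parallel.  The inverse is exact.
    """
    if data.crs_tag != "geographic-lonlat":
        raise ValueError("project_to_planar expects geographic-lonlat input")
    if method != "equirectangular":
        raise ValueError(f"unknown projection method: {method!r}")
    if np.any(np.abs(data.y) > 90.0):
        raise InvalidCoordinateError("latitude outside [-90, 90]")
    if origin is None:
        origin = (float(data.x.mean()), float(data.y.mean()))
    lon0, lat0 = origin
    k = EARTH_RADIUS_KM * math.pi / 180.0
    px = k * math.cos(math.radians(lat0)) * (data.x - lon0)
    py = k * (data.y - lat0)
    return replace(data, x=px, y=py, crs_tag="planar-km", proj_origin=(lon0, lat0))


def unproject_to_lonlat(data: PointDataset) -> PointDataset:
    """Exact inverse of :func:`project_to_planar`."""
    if data.crs_tag != "planar-km" or data.proj_origin is None:
        raise ValueError("dataset was not produced by project_to_planar")
    lon0, lat0 = data.proj_origin
    k = EARTH_RADIUS_KM * math.pi / 180.0
    lon = data.x / (k * math.cos(math.radians(lat0))) + lon0
    lat = data.y / k + lat0
    return replace(data, x=lon, y=lat, crs_tag="geographic-lonlat")


def planar_to_lonlat(
    xy: np.ndarray, proj_origin: tuple[float, float]
) -> np.ndarray:
    """Invert the equirectangular frame for arbitrary planar coordinates."""
    lon0, lat0 = proj_origin
    k = EARTH_RADIUS_KM * math.pi / 180.0
    xy = np.asarray(xy, dtype=float)
    lon = xy[:, 0] / (k * math.cos(math.radians(lat0))) + lon0
    lat = xy[:, 1] / k + lat0
    return np.column_stack([lon, lat])


def _hexagon(cx: float, cy: float, s: float, orientation: str) -> Polygon:
    if orientation == "flat-top":
        angles = np.arange(6) * 60.0
    else:  # pointy-top
        angles = np.arange(6) * 60.0 + 30.0
    rad = np.radians(angles)
    return Polygon(np.column_stack([cx + s * np.cos(rad), cy + s * np.sin(rad)]))


@dataclass
class HexLayer:
    """A regular hexagonal tessellation with optional per-cell aggregates.

    Cells are identified by index into ``centers``.  ``cell_values`` is NaN
    for cells whose point count is below the aggregation ``min_count``.
    """

    side_length: float
    orientation: str
    centers: np.ndarray  # (n, 2)
    cell_values: np.ndarray | None = None
    cell_counts: np.ndarray | None = None
    proj_origin: tuple[float, float] | None = None
    _polygons: list | None = field(default=None, repr=False)

    @property
    def n_cells(self) -> int:
        return len(self.centers)

    @property
    def polygons(self) -> list:
        if self._polygons is None:
            self._polygons = [
                _hexagon(cx, cy, self.side_length, self.orientation)
                for cx, cy in self.centers
            ]
        return self._polygons

    def nonempty_mask(self) -> np.ndarray:
        if self.cell_values is None:
            raise EmptyLayerError("layer carries no aggregated values")
        return ~np.isnan(self.cell_values)

    def nonempty(self) -> "HexLayer":
        """Restrict to cells that received an aggregate value."""
        m = self.nonempty_mask()
        return HexLayer(
            side_length=self.side_length,
            orientation=self.orientation,
            centers=self.centers[m],
            cell_values=self.cell_values[m],
            cell_counts=self.cell_counts[m],
            proj_origin=self.proj_origin,
        )

    # ---- I/O -------------------------------------------------------------

    def to_geojson(self, path: str | None = None) -> dict:
        """GeoJSON FeatureCollection of cell polygons (lon/lat if the layer
        knows its projection origin, planar km otherwise)."""
        feats = []
        for i, poly in enumerate(self.polygons):
            if self.proj_origin is not None:
                ring = planar_to_lonlat(
                    np.asarray(poly.exterior.coords), self.proj_origin
                )
                geom = mapping(Polygon(ring))
            else:
                geom = mapping(poly)
            props: dict = {"cell_id": i}
            if self.cell_values is not None:
                v = self.cell_values[i]
                props["value"] = None if np.isnan(v) else float(v)
                props["count"] = int(self.cell_counts[i])
            feats.append({"type": "Feature", "geometry": geom, "properties": props})
        gj = {"type": "FeatureCollection", "features": feats}
        if path is not None:
            with open(path, "w") as fh:
                json.dump(gj, fh)
        return gj

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["cell_id", "center_x", "center_y", "value", "count"])
            for i, (cx, cy) in enumerate(self.centers):
                v = c = ""
                if self.cell_values is not None:
                    if not np.isnan(self.cell_values[i]):
                        v = repr(float(self.cell_values[i]))
                    c = int(self.cell_counts[i])
                w.writerow([i, repr(float(cx)), repr(float(cy)), v, c])


def _center_lattice(
    bbox: tuple[float, float, float, float], s: float, orientation: str
) -> np.ndarray:
    """Hexagon centre lattice anchored at the bbox lower-left corner,
    generously covering the bbox (trimmed afterwards)."""
    xmin, ymin, xmax, ymax = bbox
    if orientation == "flat-top":
        dx, dy = 1.5 * s, math.sqrt(3.0) * s
        ncol = int(math.ceil((xmax - xmin) / dx)) + 3
        nrow = int(math.ceil((ymax - ymin) / dy)) + 3
        centers = []
        for col in range(-1, ncol):
            cx = xmin + col * dx
            off = 0.5 * dy if (col % 2) else 0.0
            for row in range(-1, nrow):
                centers.append((cx, ymin + row * dy + off))
    else:  # pointy-top: mirror of the flat-top lattice
        dx, dy = math.sqrt(3.0) * s, 1.5 * s
        ncol = int(math.ceil((xmax - xmin) / dx)) + 3
        nrow = int(math.ceil((ymax - ymin) / dy)) + 3
        centers = []
        for row in range(-1, nrow):
            cy = ymin + row * dy
            off = 0.5 * dx if (row % 2) else 0.0
            for col in range(-1, ncol):
                centers.append((xmin + col * dx + off, cy))
    return np.asarray(centers, dtype=float)


def make_hex_grid(
    bbox: tuple[float, float, float, float],
    side_length: float,
    orientation: str = "flat-top",
    proj_origin: tuple[float, float] | None = None,
) -> HexLayer:
    """Tessellate ``bbox`` with regular hexagons of the given side length.

    The lattice is anchored with one hexagon centre at the bbox lower-left
    corner (a deliberately exposed, MAUP-relevant choice: shifting the
    anchor changes every aggregate).  Only cells whose interior overlaps
    the bbox are kept, so every bbox point lies in exactly one cell.
    """
    xmin, ymin, xmax, ymax = bbox
    if side_length <= 0:
        raise ValueError("side_length must be positive")
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("bbox is degenerate")
    if side_length > (xmax - xmin) and side_length > (ymax - ymin):
        warnings.warn(
            "hexagon side exceeds both bbox dimensions; layer may collapse "
            "to a single cell",
            stacklevel=2,
        )
    centers = _center_lattice(bbox, side_length, orientation)
    # keep cells with positive-area overlap with the bbox
    box = Polygon(
        [(xmin, ymin), (xmax, ymin), (xmax, ymax), (xmin, ymax)]
    )
    keep = []
    for i, (cx, cy) in enumerate(centers):
        poly = _hexagon(cx, cy, side_length, orientation)
        if poly.intersection(box).area > 1e-12 * side_length**2:
            keep.append(i)
    return HexLayer(
        side_length=side_length,
        orientation=orientation,
        centers=centers[keep],
        proj_origin=proj_origin,
    )


def assign_cells(layer: HexLayer, coords: np.ndarray) -> np.ndarray:
    """Map each planar point to its hexagon (Voronoi of the centre lattice).

    Boundary ties go to the cell whose centre is lexicographically smallest
    in (x, y).  Returns -1 for points outside every kept cell.
    """
    coords = np.asarray(coords, dtype=float)
    tree = cKDTree(layer.centers)
    k = min(3, layer.n_cells)
    dist, idx = tree.query(coords, k=k)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    out = idx[:, 0].copy()
    tol = 1e-9 * layer.side_length
    ties = dist[:, 1:] - dist[:, [0]] < tol if k > 1 else None
    if ties is not None and ties.any():
        centers = layer.centers
        for r in np.nonzero(ties.any(axis=1))[0]:
            cand = idx[r, np.concatenate(([True], ties[r]))]
            keys = [(centers[c, 0], centers[c, 1], c) for c in cand]
            out[r] = min(keys)[2]
    # a point further than one circumradius from every kept centre lies in a
    # trimmed-away cell
    out[dist[:, 0] > layer.side_length + tol] = -1
    return out


def aggregate(
    data: PointDataset,
    layer: HexLayer,
    statistic: Statistic = "mean",
    min_count: int = 1,
) -> HexLayer:
    """Aggregate point values into the layer's cells.

    Cells with fewer than ``min_count`` points carry NaN and are excluded
    from downstream spatial-weights graphs.
    """
    if data.crs_tag != "planar-km":
        raise ValueError("aggregate expects planar-km data; project first")
    if statistic not in ("mean", "median", "max"):
        raise ValueError(f"unknown statistic: {statistic!r}")
    cell = assign_cells(layer, data.coords)
    inside = cell >= 0
    counts = np.bincount(cell[inside], minlength=layer.n_cells)
    values = np.full(layer.n_cells, np.nan)
    func = {"mean": np.mean, "median": np.median, "max": np.max}[statistic]
    for c in np.nonzero(counts >= max(min_count, 1))[0]:
        values[c] = func(data.values[inside][cell[inside] == c])
    if not np.any(~np.isnan(values)):
        raise EmptyLayerError("aggregation produced zero non-empty cells")
    return HexLayer(
        side_length=layer.side_length,
        orientation=layer.orientation,
        centers=layer.centers,
        cell_values=values,
        cell_counts=counts,
        proj_origin=layer.proj_origin,
    )


def points_to_csv(data: PointDataset, path: str) -> None:
    """Canonical points CSV (site_key, lon/x, lat/y, date, value)."""
    geo = data.crs_tag == "geographic-lonlat"
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["site_key", "lon" if geo else "x_km", "lat" if geo else "y_km",
             "date", "value"]
        )
        for i in range(len(data)):
            w.writerow(
                [
                    "" if data.site is None else data.site[i],
                    repr(float(data.x[i])),
                    repr(float(data.y[i])),
                    "" if data.date is None else data.date[i],
                    repr(float(data.values[i])),
                ]
            )
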
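"""Grid geometry, raster/point/vector containers and plain-text file I/O.

Rasters live on a shared :class:`GridSpec` (square cells, row 0 = northernmost
row, projected metre coordinates) and are persisted as single-band ESRI ASCII
grids (``.asc``) with an optional ``.prj`` sidecar carrying the CRS tag.
Point samples travel as CSV (``id,x,y,value``), vector layers as GeoJSON.
"""

from __future__ import annotations

import csv
import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import shape as shapely_shape
from shapely.geometry import mapping as shapely_mapping
from shapely.geometry.base import BaseGeometry


class DegenerateInputError(ValueError):
    """Raised when an operation is mathematically undefined for its input
    (constant layer under min-max scaling, zero-variance Moran variable...)."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up raster grid with square cells.

    ``origin_x``/``origin_y`` are the projected coordinates (metres) of the
    *outer top-left corner*; the centre of cell (row r, col c) is
    ``(origin_x + (c+0.5)*cell_size, origin_y - (r+0.5)*cell_size)``.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 500.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_tag: str = ""

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer grid rectangle."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (n_rows, n_cols) of x and y centre coordinates."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.broadcast_to(x, self.shape).copy(), np.broadcast_to(
            y[:, None], self.shape
        ).copy()

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing (x, y).

        Containment is half-open: a point on a shared edge belongs to the
        cell to its right / below, so sampling is deterministic.
        """
        col = math.floor((x - self.origin_x) / self.cell_size)
        row = math.floor((self.origin_y - y) / self.cell_size)
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({x}, {y}) outside grid bounds {self.bounds}")
        return row, col

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.bounds
        return xmin <= x < xmax and ymin < y <= ymax


@dataclass
class RasterLayer:
    """A named float grid on a :class:`GridSpec`; nodata is ``NaN``."""

    spec: GridSpec
    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.spec.shape}"
            )
        finite_or_nan = np.isfinite(self.values) | np.isnan(self.values)
        if not finite_or_nan.all():
            raise ValueError("raster values must be finite or NaN")

    def copy(self, name: str | None = None) -> "RasterLayer":
        return RasterLayer(self.spec, name or self.name, self.values.copy())

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)


@dataclass(frozen=True)
class StationSample:
    """A point observation: NO2 (ug/m3) or a meteorological quantity."""

    station_id: str
    x: float
    y: float
    value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError(f"station {self.station_id}: value must be finite")


@dataclass
class VectorLayer:
    """Weighted geometries: POIs (weight 1), roads, population blocks."""

    kind: str  # "points" | "polylines" | "polygons"
    geometries: list[BaseGeometry]
    weights: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("points", "polylines", "polygons"):
            raise ValueError(f"unknown vector kind {self.kind!r}")
        if not self.weights:
            self.weights = [1.0] * len(self.geometries)
        if len(self.weights) != len(self.geometries):
            raise ValueError("one weight per geometry required")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")


# ---------------------------------------------------------------------------
# Raster I/O (ESRI ASCII grid)
# ---------------------------------------------------------------------------

_NODATA = -9999.0


def write_raster(layer: RasterLayer, path: str | os.PathLike) -> None:
    """Write a layer as an ESRI ASCII grid; NaN becomes the nodata flag.

    The CRS tag, when non-empty, goes to a ``.prj`` sidecar.
    """
    spec = layer.spec
    vals = np.where(np.isnan(layer.values), _NODATA, layer.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.origin_x!r}\n")
        fh.write(f"yllcorner {spec.origin_y - spec.n_rows * spec.cell_size!r}\n")
        fh.write(f"cellsize {spec.cell_size!r}\n")
        fh.write(f"NODATA_value {_NODATA!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")
    if spec.crs_tag:
        with open(str(path) + ".prj", "w") as fh:
            fh.write(spec.crs_tag)


def read_raster(path: str | os.PathLike, name: str | None = None) -> RasterLayer:
    """Read a single-band ESRI ASCII grid; nodata maps to NaN."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    missing = required - header.keys()
    if missing:
        raise ValueError(f"{path}: malformed ASCII grid, missing {sorted(missing)}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    values = np.array(rows, dtype=float)
    if values.shape != (n_rows, n_cols):
        raise ValueError(
            f"{path}: data block {values.shape} does not match header "
            f"({n_rows}, {n_cols})"
        )
    nodata = header.get("nodata_value")
    if nodata is not None:
        values[values == nodata] = np.nan
    crs_tag = ""
    prj = str(path) + ".prj"
    if os.path.exists(prj):
        with open(prj) as fh:
            crs_tag = fh.read().strip()
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=header["cellsize"],
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * header["cellsize"],
        crs_tag=crs_tag,
    )
    return RasterLayer(spec, name or os.path.splitext(os.path.basename(path))[0], values)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def sample_at(layer: RasterLayer, x: float, y: float) -> float:
    """Value of the cell containing (x, y); nodata propagates as NaN."""
    row, col = layer.spec.cell_of(x, y)
    return float(layer.values[row, col])


def sample_many(layer: RasterLayer, xs: Sequence[float], ys: Sequence[float]) -> np.ndarray:
    return np.array([sample_at(layer, x, y) for x, y in zip(xs, ys)])


def resample_to(layer: RasterLayer, spec: GridSpec) -> RasterLayer:
    """Nearest-neighbour resampling: each target cell takes the source value
    at its own centre; target cells outside the source extent become NaN."""
    sxmin, symin, sxmax, symax = layer.spec.bounds
    txmin, tymin, txmax, tymax = spec.bounds
    if txmin >= sxmax or txmax <= sxmin or tymin >= symax or tymax <= symin:
        raise ValueError("source and target extents are disjoint")
    cx, cy = spec.cell_centers()
    out = np.full(spec.shape, np.nan)
    for r in range(spec.n_rows):
        for c in range(spec.n_cols):
            if layer.spec.contains(cx[r, c], cy[r, c]):
                out[r, c] = sample_at(layer, cx[r, c], cy[r, c])
    return RasterLayer(spec, layer.name, out)


# ---------------------------------------------------------------------------
# Point and vector I/O
# ---------------------------------------------------------------------------


def write_points(samples: Iterable[StationSample], path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "x", "y", "value"])
        for s in samples:
            writer.writerow(
                [s.station_id, repr(float(s.x)), repr(float(s.y)), repr(float(s.value))]
            )


def read_points(path: str | os.PathLike) -> list[StationSample]:
    """Read station samples from CSV with header ``id,x,y,value``."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        cols = set(reader.fieldnames or [])
        if not {"id", "x", "y", "value"} <= cols:
            raise ValueError(f"{path}: CSV must have columns id,x,y,value, got {cols}")
        return [
            StationSample(row["id"], float(row["x"]), float(row["y"]), float(row["value"]))
            for row in reader
        ]


_GEOJSON_KIND = {
    "Point": "points",
    "MultiPoint": "points",
    "LineString": "polylines",
    "MultiLineString": "polylines",
    "Polygon": "polygons",
    "MultiPolygon": "polygons",
}


def write_vector(layer: VectorLayer, path: str | os.PathLike) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": shapely_mapping(geom),
            "properties": {"weight": w},
        }
        for geom, w in zip(layer.geometries, layer.weights)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_vector(path: str | os.PathLike) -> VectorLayer:
    """Read a GeoJSON FeatureCollection; a ``weight`` property is carried
    through (default 1). All features must share one geometry family."""
    with open(path) as fh:
        doc = json.load(fh)
    feats = doc.get("features", [])
    if not feats:
        return VectorLayer("points", [], [])
    geometries, weights, kinds = [], [], set()
    for feat in feats:
        try:
            geom = shapely_shape(feat["geometry"])
        except Exception as exc:  # unparseable geometry
            raise ValueError(f"{path}: unparseable geometry: {exc}") from exc
        kind = _GEOJSON_KIND.get(geom.geom_type)
        if kind is None:
            raise ValueError(f"{path}: unsupported geometry {geom.geom_type}")
        kinds.add(kind)
        geometries.append(geom)
        weights.append(float((feat.get("properties") or {}).get("weight", 1.0)))
    if len(kinds) > 1:
        raise ValueError(f"{path}: mixed geometry kinds {sorted(kinds)}")
    return VectorLayer(kinds.pop(), geometries, weights)
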
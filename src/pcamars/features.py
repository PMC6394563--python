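"""Covariate engineering: the 14-layer normalized feature stack.

Raw inputs (meteorological point samples, a DEM, POI/road/population vector
layers) are turned into rasters on one grid:

* meteorological variables -> IDW surfaces with an LOOCV-selected power,
* DEM -> resampled elevation plus a focal-mean "average elevation" layer,
* POIs / roads / population -> planar kernel density (quartic kernel),

with the neighbourhood radius of every focal/KDE layer chosen by maximizing
the magnitude of the bivariate Moran's I between the candidate surface
(sampled at the monitoring stations) and the dependent variable. All layers
are min-max normalized to [0, 1]; the two coordinate layers are the raw
cell-centre x and y, normalized the same way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .grid import (
    DegenerateInputError,
    GridSpec,
    RasterLayer,
    StationSample,
    VectorLayer,
    resample_to,
    sample_many,
)

#: canonical order of the 14 covariates
FEATURE_NAMES = (
    "wind_speed",
    "temperature",
    "pressure",
    "relative_humidity",
    "gas_density",
    "petrol_density",
    "green_density",
    "sport_density",
    "dem",
    "avg_elevation",
    "population_density",
    "road_density",
    "x_coord",
    "y_coord",
)


@dataclass
class RadiusSearchResult:
    """Candidate radii, their bivariate Moran's I values and the winner."""

    radii: list[float]
    moran_values: list[float]
    selected_radius: float


@dataclass
class FeatureStack:
    """The ordered, normalized 14-layer covariate set on one grid."""

    spec: GridSpec
    layers: list[RasterLayer]
    normalization_bounds: dict[str, tuple[float, float]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(l.name for l in self.layers) != FEATURE_NAMES:
            raise ValueError("stack must hold the 14 canonical layers in order")
        if any(l.spec != self.spec for l in self.layers):
            raise ValueError("all layers must share the stack grid")

    @property
    def valid_mask(self) -> np.ndarray:
        mask = np.ones(self.spec.shape, dtype=bool)
        for layer in self.layers:
            mask &= layer.valid_mask
        return mask

    def to_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_valid_pixels x 14 matrix, flat boolean valid mask)."""
        mask = self.valid_mask.ravel()
        cols = [l.values.ravel()[mask] for l in self.layers]
        return np.column_stack(cols), mask

    def rows_at(self, xs: Sequence[float], ys: Sequence[float]) -> np.ndarray:
        """14-vector per point, sampled from the normalized layers."""
        return np.column_stack([sample_many(l, xs, ys) for l in self.layers])


# ---------------------------------------------------------------------------
# Interpolators and neighbourhood statistics
# ---------------------------------------------------------------------------


def idw_surface(
    samples: Sequence[StationSample], spec: GridSpec, power: float, name: str = "idw"
) -> RasterLayer:
    """Inverse-distance-weighted surface: cell = sum(w_i v_i)/sum(w_i) with
    w_i = d_i**-power; a cell whose centre coincides with a sample (within
    cell_size/1000) takes that sample's value exactly."""
    if not samples:
        raise ValueError("idw_surface needs at least one sample")
    if power <= 0:
        raise ValueError("power must be positive")
    cx, cy = spec.cell_centers()
    sx = np.array([s.x for s in samples])
    sy = np.array([s.y for s in samples])
    sv = np.array([s.value for s in samples])
    d = np.hypot(cx[..., None] - sx, cy[..., None] - sy)  # (rows, cols, n)
    eps = spec.cell_size / 1000.0
    hit = d < eps
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    w[hit.any(axis=-1)] = 0.0  # replaced by the exact sample value below
    out = np.where(
        hit.any(axis=-1),
        sv[np.argmax(hit, axis=-1)],
        (w * sv).sum(axis=-1) / np.where(w.sum(axis=-1) == 0, 1, w.sum(axis=-1)),
    )
    return RasterLayer(spec, name, out)


def idw_predict(
    train: Sequence[StationSample], x: float, y: float, power: float
) -> float:
    """Point-to-point IDW prediction (used for power selection and the IDW
    baseline)."""
    d = np.hypot(
        np.array([s.x for s in train]) - x, np.array([s.y for s in train]) - y
    )
    v = np.array([s.value for s in train])
    if d.min() == 0:
        return float(v[int(np.argmin(d))])
    w = d ** (-power)
    return float((w * v).sum() / w.sum())


def select_idw_power(
    samples: Sequence[StationSample], candidate_powers: Sequence[float]
) -> float:
    """Pick the candidate power minimizing LOOCV RMSE of point-to-point IDW;
    ties break toward the smallest power."""
    if len(samples) < 3:
        raise ValueError("power selection needs at least 3 samples")
    if not candidate_powers:
        raise ValueError("no candidate powers")
    best_power, best_rmse = None, np.inf
    for p in sorted(candidate_powers):
        sq = 0.0
        for i, s in enumerate(samples):
            rest = [t for j, t in enumerate(samples) if j != i]
            sq += (idw_predict(rest, s.x, s.y, p) - s.value) ** 2
        rmse = math.sqrt(sq / len(samples))
        # tolerance so numerically identical scores tie toward the
        # smallest power instead of resolving by rounding noise
        if best_power is None or rmse < best_rmse - 1e-9 * max(1.0, best_rmse):
            best_power, best_rmse = p, rmse
    return float(best_power)


def _disc_offsets(radius: float, cell_size: float) -> np.ndarray:
    """Binary footprint of cells whose centres lie strictly within radius
    (metres); strict, so a one-cell radius is a singleton neighbourhood."""
    k = int(math.ceil(radius / cell_size))
    di = np.arange(-k, k + 1)
    mask = (di[:, None] ** 2 + di[None, :] ** 2) * cell_size**2 < radius**2
    return mask.astype(float)


def focal_mean(layer: RasterLayer, radius: float) -> RasterLayer:
    """Circular-neighbourhood mean (centre included); nodata cells are
    excluded from the mean and stay nodata in the output."""
    if radius < layer.spec.cell_size:
        raise ValueError("radius must be at least one cell")
    foot = _disc_offsets(radius, layer.spec.cell_size)
    vals = layer.values
    nan = np.isnan(vals)
    num = fftconvolve(np.where(nan, 0.0, vals), foot, mode="same")
    den = fftconvolve((~nan).astype(float), foot, mode="same")
    den = np.round(den)  # counts are integers; kill fft jitter
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / np.where(den == 0, 1, den), np.nan)
    out[nan] = np.nan
    return RasterLayer(layer.spec, f"{layer.name}_focal", out)


def _layer_to_weighted_points(
    layer: VectorLayer, cell_size: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse a vector layer to weighted points for planar KDE.

    Points keep their weight; polylines are densified every cell_size/2 with
    each sampled point weighted by the length it represents; polygons
    contribute their centroid carrying the polygon weight (population).
    """
    xs: list[float] = []
    ys: list[float] = []
    ws: list[float] = []
    step = cell_size / 2.0
    for geom, w in zip(layer.geometries, layer.weights):
        if layer.kind == "points":
            for part in getattr(geom, "geoms", [geom]):
                xs.append(part.x)
                ys.append(part.y)
                ws.append(w)
        elif layer.kind == "polylines":
            for part in getattr(geom, "geoms", [geom]):
                length = part.length
                if length == 0:
                    continue
                n = max(1, int(math.ceil(length / step)))
                seg = length / n
                for i in range(n):
                    pt = part.interpolate((i + 0.5) * seg)
                    xs.append(pt.x)
                    ys.append(pt.y)
                    ws.append(w * seg)
        else:  # polygons
            c = geom.centroid
            xs.append(c.x)
            ys.append(c.y)
            ws.append(w)
    return np.array(xs), np.array(ys), np.array(ws)


def kde_surface(
    points: VectorLayer, spec: GridSpec, radius: float, name: str = "kde"
) -> RasterLayer:
    """Planar kernel density with the quartic (biweight) kernel.

    cell value = sum_j w_j * K(d_j / radius) / radius^2 with
    K(u) = (3/pi) (1 - u^2)^2 for u < 1, else 0, so the surface integrates
    to the total weight. An empty layer yields an all-zero raster.
    """
    if radius < spec.cell_size:
        raise ValueError("radius must be at least one cell")
    out = np.zeros(spec.shape)
    px, py, pw = _layer_to_weighted_points(points, spec.cell_size)
    if px.size == 0:
        return RasterLayer(spec, name, out)
    cell = spec.cell_size
    k_cells = int(math.ceil(radius / cell)) + 1
    cols_x = spec.origin_x + (np.arange(spec.n_cols) + 0.5) * cell
    rows_y = spec.origin_y - (np.arange(spec.n_rows) + 0.5) * cell
    for x, y, w in zip(px, py, pw):
        c0 = int((x - spec.origin_x) // cell)
        r0 = int((spec.origin_y - y) // cell)
        c_lo, c_hi = max(0, c0 - k_cells), min(spec.n_cols, c0 + k_cells + 1)
        r_lo, r_hi = max(0, r0 - k_cells), min(spec.n_rows, r0 + k_cells + 1)
        if c_lo >= c_hi or r_lo >= r_hi:
            continue
        dx = cols_x[c_lo:c_hi] - x
        dy = rows_y[r_lo:r_hi] - y
        u2 = (dx[None, :] ** 2 + dy[:, None] ** 2) / radius**2
        inside = u2 < 1.0
        out[r_lo:r_hi, c_lo:c_hi] += np.where(
            inside, w * (3.0 / math.pi) * (1.0 - u2) ** 2 / radius**2, 0.0
        )
    return RasterLayer(spec, name, out)


# ---------------------------------------------------------------------------
# Bivariate Moran's I and radius selection
# ---------------------------------------------------------------------------


def bivariate_morans_i(
    dep: Sequence[float], cov: Sequence[float], weights: np.ndarray
) -> float:
    """Cross Moran's I between ``dep`` and the spatial lag of ``cov``:

        I = (n / S0) * sum_ij w_ij z_i c_j / sqrt(sum z^2 * sum c^2)

    with z, c the mean-centred variables and S0 the weight total. The weight
    matrix must be non-negative with a zero diagonal.
    """
    z = np.asarray(dep, dtype=float)
    c = np.asarray(cov, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = z.size
    if n < 3 or c.size != n or w.shape != (n, n):
        raise ValueError("need equal-length variables (n>=3) and an n x n weight matrix")
    if (w < 0).any() or np.diag(w).any():
        raise ValueError("weights must be non-negative with zero diagonal")
    z = z - z.mean()
    c = c - c.mean()
    sz, sc = (z**2).sum(), (c**2).sum()
    if sz == 0 or sc == 0:
        raise DegenerateInputError("zero variance: Moran's I undefined")
    s0 = w.sum()
    if s0 == 0:
        raise ValueError("weight matrix sums to zero")
    return float((n / s0) * (z @ w @ c) / math.sqrt(sz * sc))


def inverse_distance_weights(
    xs: Sequence[float], ys: Sequence[float], power: float = 1.0
) -> np.ndarray:
    """Station spatial-weight matrix: inverse distance, zero diagonal."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    d = np.hypot(x[:, None] - x, y[:, None] - y)
    with np.errstate(divide="ignore"):
        w = d ** (-power)
    np.fill_diagonal(w, 0.0)
    w[~np.isfinite(w)] = 0.0
    return w


def select_radius(
    dep_samples: Sequence[StationSample],
    surface_builder: Callable[[float], RasterLayer],
    radii: Sequence[float],
    weights: np.ndarray | None = None,
) -> RadiusSearchResult:
    """Sweep candidate radii; keep the one maximizing |I| between the
    dependent values and the candidate surface sampled at the stations.

    |I| rather than signed I: covariates such as green areas are expected to
    correlate *negatively* with NO2, and the search must still find the
    radius of strongest spatial association. Degenerate surfaces (constant
    at the stations) score NaN and can never win.
    """
    if len(dep_samples) < 4:
        raise ValueError("radius selection needs at least 4 stations")
    if len(radii) < 1:
        raise ValueError("no candidate radii")
    xs = [s.x for s in dep_samples]
    ys = [s.y for s in dep_samples]
    dep = [s.value for s in dep_samples]
    if weights is None:
        weights = inverse_distance_weights(xs, ys)
    morans: list[float] = []
    for r in radii:
        surface = surface_builder(r)
        cov = sample_many(surface, xs, ys)
        try:
            morans.append(bivariate_morans_i(dep, cov, weights))
        except DegenerateInputError:
            morans.append(np.nan)
    arr = np.asarray(morans)
    if np.isnan(arr).all():
        raise DegenerateInputError("covariate degenerate at every candidate radius")
    best = int(np.nanargmax(np.abs(arr)))
    return RadiusSearchResult(list(radii), morans, float(radii[best]))


def default_radius_grid(spec: GridSpec) -> list[float]:
    """1 cell up to 25% of the shorter grid extent, in 1-cell steps."""
    max_r = 0.25 * min(spec.n_rows, spec.n_cols) * spec.cell_size
    n = max(2, int(max_r // spec.cell_size))
    return [spec.cell_size * k for k in range(1, n + 1)]


# ---------------------------------------------------------------------------
# Normalization and stack assembly
# ---------------------------------------------------------------------------


def min_max_normalize(layer: RasterLayer) -> tuple[RasterLayer, tuple[float, float]]:
    """Scale to [0, 1] over non-nodata cells; returns the (min, max) bounds
    so predictions can reuse the training scaling. Constant layers are
    degenerate."""
    vals = layer.values
    lo = float(np.nanmin(vals))
    hi = float(np.nanmax(vals))
    if hi == lo:
        raise DegenerateInputError(f"layer {layer.name!r} is constant; min-max undefined")
    return RasterLayer(layer.spec, layer.name, (vals - lo) / (hi - lo)), (lo, hi)


@dataclass
class SceneInputs:
    """Raw inputs of one interpolation problem on a common grid."""

    spec: GridSpec
    dep_stations: list[StationSample]  # NO2 at monitoring stations
    met_samples: Mapping[str, list[StationSample]]  # 4 meteorological vars
    dem: RasterLayer
    poi_layers: Mapping[str, VectorLayer]  # gas, petrol, green, sport
    roads: VectorLayer
    population: VectorLayer


class FeatureStackBuilder:
    """Builds 14-layer stacks, caching every candidate surface.

    Candidate focal/KDE surfaces depend only on the radius, never on the
    dependent variable, so during leave-one-out cross-validation they are
    built once and only the Moran radius choice is repeated per fold.
    """

    MET_ORDER = ("wind_speed", "temperature", "pressure", "relative_humidity")
    KDE_ORDER = ("gas", "petrol", "green", "sport", "population", "roads")

    def __init__(
        self,
        inputs: SceneInputs,
        radii: Sequence[float] | None = None,
        idw_powers: Sequence[float] = (1.0, 2.0, 3.0),
    ):
        self.inputs = inputs
        self.spec = inputs.spec
        self.radii = list(radii) if radii is not None else default_radius_grid(self.spec)
        self.idw_powers = list(idw_powers)
        self._cache: dict[tuple[str, float], RasterLayer] = {}
        missing = [m for m in self.MET_ORDER if m not in inputs.met_samples]
        if missing:
            raise ValueError(f"missing meteorological inputs: {missing}")
        missing = [
            p for p in ("gas", "petrol", "green", "sport") if p not in inputs.poi_layers
        ]
        if missing:
            raise ValueError(f"missing POI classes: {missing}")

    def _vector(self, key: str) -> VectorLayer:
        if key == "population":
            return self.inputs.population
        if key == "roads":
            return self.inputs.roads
        return self.inputs.poi_layers[key]

    def candidate_surface(self, key: str, radius: float) -> RasterLayer:
        """KDE (vector layers) or focal-mean (DEM) surface at one radius."""
        ck = (key, radius)
        if ck not in self._cache:
            if key == "avg_elevation":
                dem = resample_to(self.inputs.dem, self.spec)
                self._cache[ck] = focal_mean(dem, radius)
            else:
                self._cache[ck] = kde_surface(
                    self._vector(key), self.spec, radius, name=f"{key}_kde"
                )
        return self._cache[ck]

    def build(
        self, dep_stations: Sequence[StationSample] | None = None
    ) -> FeatureStack:
        """Assemble the stack, selecting radii/power against ``dep_stations``
        (defaults to all stations of the scene)."""
        dep = list(dep_stations) if dep_stations is not None else self.inputs.dep_stations
        if len(dep) < 4:
            raise ValueError("need at least 4 dependent-variable stations")
        weights = inverse_distance_weights([s.x for s in dep], [s.y for s in dep])
        provenance: dict = {"radii": {}, "moran": {}}

        layers: list[RasterLayer] = []
        provenance["idw_power"] = {}
        for met in self.MET_ORDER:
            power = select_idw_power(self.inputs.met_samples[met], self.idw_powers)
            provenance["idw_power"][met] = power
            layers.append(
                idw_surface(self.inputs.met_samples[met], self.spec, power, name=met)
            )

        kde_layers: dict[str, RasterLayer] = {}
        for key in ("gas", "petrol", "green", "sport", "population", "roads"):
            res = select_radius(
                dep, lambda r, k=key: self.candidate_surface(k, r), self.radii, weights
            )
            provenance["radii"][key] = res.selected_radius
            provenance["moran"][key] = res.moran_values
            kde_layers[key] = self.candidate_surface(key, res.selected_radius)
        for key, fname in (
            ("gas", "gas_density"),
            ("petrol", "petrol_density"),
            ("green", "green_density"),
            ("sport", "sport_density"),
        ):
            layers.append(kde_layers[key].copy(name=fname))

        dem = resample_to(self.inputs.dem, self.spec).copy(name="dem")
        layers.append(dem)
        res = select_radius(
            dep, lambda r: self.candidate_surface("avg_elevation", r), self.radii, weights
        )
        provenance["radii"]["avg_elevation"] = res.selected_radius
        provenance["moran"]["avg_elevation"] = res.moran_values
        layers.append(
            self.candidate_surface("avg_elevation", res.selected_radius).copy(
                name="avg_elevation"
            )
        )

        layers.append(kde_layers["population"].copy(name="population_density"))
        layers.append(kde_layers["roads"].copy(name="road_density"))

        cx, cy = self.spec.cell_centers()
        layers.append(RasterLayer(self.spec, "x_coord", cx))
        layers.append(RasterLayer(self.spec, "y_coord", cy))

        normalized: list[RasterLayer] = []
        bounds: dict[str, tuple[float, float]] = {}
        for layer in layers:
            norm, bb = min_max_normalize(layer)
            normalized.append(norm)
            bounds[layer.name] = bb
        return FeatureStack(self.spec, normalized, bounds, provenance)


def build_feature_stack(
    inputs: SceneInputs,
    radii: Sequence[float] | None = None,
    idw_powers: Sequence[float] = (1.0, 2.0, 3.0),
) -> FeatureStack:
    """One-shot stack construction (see :class:`FeatureStackBuilder`)."""
    return FeatureStackBuilder(inputs, radii, idw_powers).build()
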
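"""End-to-end orchestration: featurize -> PCA -> MARS -> predicted map,
plus the LOOCV comparison harness against the reference interpolators."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import pca as pca_mod
from .baselines import (
    fit_mars3,
    krige_auto,
    mars3_predict_points,
)
from .evaluation import CvResult, FitPredict, compare_methods
from .features import FeatureStack, FeatureStackBuilder, SceneInputs
from .grid import RasterLayer, StationSample, sample_many, write_raster
from .mars import MarsConfig, MarsModel, fit_mars, model_to_dict, predict
from .mars import model_from_dict  # noqa: F401  (re-exported for loaders)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline in one declarative object. The YAML
    config file mirrors these keys."""

    pca_components: int = 3
    mars: MarsConfig = field(default_factory=MarsConfig)
    idw_powers: tuple[float, ...] = (1.0, 2.0, 3.0)
    radii: list[float] | None = None  # None -> default 1-cell-step grid
    freeze_radii: bool = False  # reuse all-station radii inside CV folds
    clip_scores: bool = True  # clamp prediction-time PC scores to the training hull

    @staticmethod
    def from_yaml(path: str) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        mars_doc = doc.get("mars", {})
        return PipelineConfig(
            pca_components=int(doc.get("pca_components", 3)),
            mars=MarsConfig(
                max_terms=mars_doc.get("max_terms"),
                max_degree=int(mars_doc.get("max_degree", 2)),
                penalty=float(mars_doc.get("penalty", 3.0)),
            ),
            idw_powers=tuple(doc.get("idw_powers", (1.0, 2.0, 3.0))),
            radii=doc.get("radii"),
            freeze_radii=bool(doc.get("freeze_radii", False)),
            clip_scores=bool(doc.get("clip_scores", True)),
        )


@dataclass
class PcamarsResult:
    """A fitted pipeline: the NO2 map, the MARS model in PC space, the PCA
    transform, the feature stack and full provenance (selected radii, IDW
    powers, basis functions, GCV)."""

    map: RasterLayer
    model: MarsModel
    pca: pca_mod.PcaTransform
    stack: FeatureStack
    provenance: dict


def _clip_to_hull(scores: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Clamp prediction-time predictors to the training range per column.

    Hinge models are linear beyond the last knot, so evaluating them outside
    the observed design space extrapolates without support; clamping holds
    the prediction at the nearest boundary of the training hull instead."""
    return np.clip(scores, lo, hi)


def _fit_on_stack(
    stack: FeatureStack,
    stations: Sequence[StationSample],
    config: PipelineConfig,
) -> tuple[MarsModel, pca_mod.PcaTransform, np.ndarray, np.ndarray]:
    X_pix, _ = stack.to_matrix()
    t = pca_mod.select_components(pca_mod.fit_pca(X_pix), k=config.pca_components)
    rows = stack.rows_at([s.x for s in stations], [s.y for s in stations])
    scores = pca_mod.transform(t, rows)
    y = np.array([s.value for s in stations])
    model = fit_mars(scores, y, config.mars)
    return model, t, scores.min(axis=0), scores.max(axis=0)


def run_pcamars(
    inputs: SceneInputs, config: PipelineConfig = PipelineConfig()
) -> PcamarsResult:
    """Fit the full pipeline on all stations and predict every valid pixel."""
    if len(inputs.dep_stations) < 4:
        raise ValueError("pipeline requires at least 4 stations")
    builder = FeatureStackBuilder(inputs, config.radii, config.idw_powers)
    stack = builder.build()
    model, t, lo, hi = _fit_on_stack(stack, inputs.dep_stations, config)

    X_pix, mask = stack.to_matrix()
    scores = pca_mod.transform(t, X_pix)
    if config.clip_scores:
        scores = _clip_to_hull(scores, lo, hi)
    preds = predict(model, scores)
    grid = np.full(stack.spec.shape[0] * stack.spec.shape[1], np.nan)
    grid[mask] = preds
    no2_map = RasterLayer(stack.spec, "no2_pcamars", grid.reshape(stack.spec.shape))

    provenance = dict(stack.provenance)
    provenance["pca_explained_ratio"] = t.explained_ratio[: t.n_keep].tolist()
    provenance["mars"] = model_to_dict(model)
    log.info(
        "PCAMARS fit: radii=%s, GCV=%.4g, %d basis functions",
        provenance.get("radii"), model.gcv, len(model.basis),
    )
    return PcamarsResult(map=no2_map, model=model, pca=t, stack=stack,
                         provenance=provenance)


# ---------------------------------------------------------------------------
# LOOCV method adapters
# ---------------------------------------------------------------------------


def idw_method(powers: Sequence[float] = (1.0, 2.0, 3.0)) -> FitPredict:
    """IDW with the power selected by inner LOOCV on the training fold."""
    from .features import idw_predict, select_idw_power

    def fit_predict(train: Sequence[StationSample], target: StationSample) -> float:
        p = select_idw_power(train, powers)
        return idw_predict(train, target.x, target.y, p)

    return fit_predict


def ok_method() -> FitPredict:
    """Ordinary kriging with a spherical variogram refitted per fold."""

    def fit_predict(train: Sequence[StationSample], target: StationSample) -> float:
        return float(krige_auto(train, [target.x], [target.y])[0])

    return fit_predict


def mars3_method(dem: RasterLayer, config: MarsConfig = MarsConfig()) -> FitPredict:
    from .baselines import mars3_design

    def fit_predict(train: Sequence[StationSample], target: StationSample) -> float:
        model = fit_mars3(train, dem, config)
        D = mars3_design(train, dem)
        row = np.column_stack(
            [[target.x], [target.y], sample_many(dem, [target.x], [target.y])]
        )
        row = _clip_to_hull(row, D.min(axis=0), D.max(axis=0))
        return float(predict(model, row)[0])

    return fit_predict


def pcamars_method(
    inputs: SceneInputs, config: PipelineConfig = PipelineConfig()
) -> FitPredict:
    """PCAMARS refit per fold. Candidate focal/KDE surfaces never depend on
    the dependent variable, so they are cached across folds; the Moran
    radius choice, the PCA on the resulting stack and the MARS stage are
    refit on each fold's n-1 stations (with ``freeze_radii`` the radii —
    and hence the stack and PCA — are chosen once from all stations)."""
    builder = FeatureStackBuilder(inputs, config.radii, config.idw_powers)
    frozen: dict = {}
    if config.freeze_radii:
        frozen["stack"] = builder.build()

    def fit_predict(train: Sequence[StationSample], target: StationSample) -> float:
        stack = frozen["stack"] if config.freeze_radii else builder.build(train)
        model, t, lo, hi = _fit_on_stack(stack, train, config)
        row = stack.rows_at([target.x], [target.y])
        score = pca_mod.transform(t, row)
        if config.clip_scores:
            score = _clip_to_hull(score, lo, hi)
        return float(predict(model, score)[0])

    return fit_predict


ALL_METHODS = ("idw", "ok", "mars3", "pcamars")


def run_crossval(
    inputs: SceneInputs,
    methods: Sequence[str] = ALL_METHODS,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[pd.DataFrame, Mapping[str, CvResult]]:
    """LOOCV RMSE comparison table over the requested methods."""
    fps: dict[str, FitPredict] = {}
    for name in methods:
        if name == "idw":
            fps[name] = idw_method(config.idw_powers)
        elif name == "ok":
            fps[name] = ok_method()
        elif name == "mars3":
            fps[name] = mars3_method(inputs.dem, config.mars)
        elif name == "pcamars":
            fps[name] = pcamars_method(inputs, config)
        else:
            raise ValueError(f"unknown method {name!r}")
    return compare_methods(inputs.dep_stations, fps)


def save_result(result: PcamarsResult, directory: str | Path) -> None:
    """Persist the map, the MARS model, the PCA transform and provenance."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_raster(result.map, d / "no2_map.asc")
    with open(d / "mars_model.json", "w") as fh:
        json.dump(model_to_dict(result.model), fh, indent=1)
    pca_mod.save_pca(result.pca, d / "pca.json")
    with open(d / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=1, default=float)
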
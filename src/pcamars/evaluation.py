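"""Leave-one-out cross-validation, RMSE scoring and method comparison."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import StationSample

log = logging.getLogger(__name__)

#: a method trains on n-1 stations and predicts at the held-out one
FitPredict = Callable[[Sequence[StationSample], StationSample], float]


def rmse(obs: Sequence[float], pred: Sequence[float]) -> float:
    """Root-mean-square error sqrt(n^-1 sum |y_i - yhat_i|^2)."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size == 0:
        raise ValueError("obs and pred must be equal-length non-empty vectors")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


@dataclass
class CvResult:
    """Per-station LOOCV pairs and the resulting RMSE for one method."""

    method: str
    station_ids: list[str]
    observed: list[float]
    predicted: list[float]

    @property
    def rmse(self) -> float:
        return rmse(self.observed, self.predicted)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "method": self.method,
                "station_id": self.station_ids,
                "observed": self.observed,
                "predicted": self.predicted,
            }
        )


def loocv(
    fit_predict: FitPredict,
    stations: Sequence[StationSample],
    method: str = "method",
) -> CvResult:
    """n folds; fold i trains on all stations but i and predicts station i's
    value at its location. A fold failure aborts with the fold index."""
    if len(stations) < 3:
        raise ValueError("LOOCV needs at least 3 stations")
    ids, obs, pred = [], [], []
    for i, held_out in enumerate(stations):
        train = [s for j, s in enumerate(stations) if j != i]
        try:
            yhat = float(fit_predict(train, held_out))
        except Exception as exc:
            raise RuntimeError(f"{method}: LOOCV fold {i} failed: {exc}") from exc
        ids.append(held_out.station_id)
        obs.append(held_out.value)
        pred.append(yhat)
    return CvResult(method, ids, obs, pred)


def compare_methods(
    stations: Sequence[StationSample],
    methods: Mapping[str, FitPredict],
) -> tuple[pd.DataFrame, dict[str, CvResult]]:
    """LOOCV every method on the same stations; returns the RMSE table
    sorted ascending plus the per-method fold detail. A failing method is
    dropped from the table with a logged warning."""
    rows, details = [], {}
    for name, fp in methods.items():
        try:
            res = loocv(fp, stations, method=name)
        except Exception as exc:
            log.warning("method %s failed: %s", name, exc)
            continue
        details[name] = res
        rows.append({"method": name, "rmse": res.rmse})
    table = pd.DataFrame(rows).sort_values("rmse", ignore_index=True) if rows else (
        pd.DataFrame(columns=["method", "rmse"])
    )
    return table, details
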
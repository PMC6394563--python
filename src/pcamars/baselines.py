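"""Reference interpolators: IDW, ordinary kriging with a spherical
semivariogram, and MARS3 (a MARS fit on latitude, longitude and elevation
only)."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .grid import GridSpec, RasterLayer, StationSample, sample_many
from .mars import MarsConfig, MarsModel, fit_mars, predict as mars_predict

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SphericalVariogram:
    """gamma(h) = nugget + psill * (1.5 h/a - 0.5 (h/a)^3) below the range a,
    the full sill beyond it, and exactly 0 at h = 0."""

    nugget: float
    partial_sill: float
    range_m: float

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.partial_sill < 0 or self.range_m <= 0:
            raise ValueError("need nugget >= 0, partial_sill >= 0, range > 0")


def variogram_value(model: SphericalVariogram, h: float | np.ndarray) -> np.ndarray:
    h = np.asarray(h, dtype=float)
    r = np.clip(h / model.range_m, 0.0, 1.0)
    g = model.nugget + model.partial_sill * (1.5 * r - 0.5 * r**3)
    return np.where(h == 0, 0.0, g)


def empirical_semivariogram(
    samples: Sequence[StationSample], n_bins: int = 10
) -> list[tuple[float, float, int]]:
    """Method-of-moments semivariogram: per lag bin, the mean of
    0.5 (v_i - v_j)^2 over station pairs, binned at equal width up to half
    the maximum pairwise distance. Returns (lag centre, semivariance, pairs)
    for the non-empty bins."""
    if len(samples) < 4:
        raise ValueError("need at least 4 samples")
    x = np.array([s.x for s in samples])
    y = np.array([s.y for s in samples])
    v = np.array([s.value for s in samples])
    iu = np.triu_indices(len(samples), k=1)
    d = np.hypot(x[:, None] - x, y[:, None] - y)[iu]
    sv = 0.5 * (v[:, None] - v) ** 2
    sv = sv[iu]
    if d.max() == 0:
        raise ValueError("all samples coincide")
    cutoff = d.max() / 2.0
    edges = np.linspace(0, cutoff, n_bins + 1)
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (d > lo) & (d <= hi)
        if in_bin.any():
            out.append(((lo + hi) / 2.0, float(sv[in_bin].mean()), int(in_bin.sum())))
    return out


def fit_spherical(
    empirical: Sequence[tuple[float, float, int]]
) -> SphericalVariogram:
    """Count-weighted least-squares fit of the spherical model, bounded to
    non-negative parameters. If the optimizer fails, falls back to a pure
    spatial-variance model (nugget 0, sill = mean semivariance, range = half
    the maximum lag) with a logged warning."""
    if len(empirical) < 3:
        raise ValueError("need at least 3 non-empty bins")
    lags = np.array([e[0] for e in empirical])
    gammas = np.array([e[1] for e in empirical])
    counts = np.array([e[2] for e in empirical], dtype=float)
    w = np.sqrt(counts / counts.sum())

    def resid(theta: np.ndarray) -> np.ndarray:
        m = SphericalVariogram(theta[0], theta[1], theta[2])
        return w * (variogram_value(m, lags) - gammas)

    sill0 = max(gammas.mean(), 1e-12)
    x0 = np.array([0.0, sill0, max(lags.max() / 2.0, 1e-6)])
    try:
        sol = least_squares(
            resid,
            x0,
            bounds=([0, 0, 1e-9], [np.inf, np.inf, np.inf]),
            xtol=1e-12,
            ftol=1e-12,
        )
        if not sol.success:
            raise RuntimeError(sol.message)
        return SphericalVariogram(*sol.x)
    except Exception as exc:
        warnings.warn(f"variogram fit failed ({exc}); using fallback parameters")
        return SphericalVariogram(0.0, sill0, max(lags.max() / 2.0, 1e-6))


def kriging_weights(
    samples: Sequence[StationSample], vario: SphericalVariogram, x: float, y: float
) -> tuple[np.ndarray, float]:
    """Solve the ordinary-kriging system at one target: returns the n
    weights (summing to 1) and the Lagrange multiplier."""
    A, _ = _ok_matrix(samples, vario)
    sx = np.array([s.x for s in samples])
    sy = np.array([s.y for s in samples])
    b = np.append(variogram_value(vario, np.hypot(sx - x, sy - y)), 1.0)
    sol = np.linalg.solve(A, b)
    return sol[:-1], float(sol[-1])


def _ok_matrix(
    samples: Sequence[StationSample], vario: SphericalVariogram
) -> tuple[np.ndarray, int]:
    n = len(samples)
    sx = np.array([s.x for s in samples])
    sy = np.array([s.y for s in samples])
    d = np.hypot(sx[:, None] - sx, sy[:, None] - sy)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = variogram_value(vario, d)
    A[n, :] = 1.0
    A[:, n] = 1.0
    A[n, n] = 0.0
    if np.linalg.cond(A) > 1e12:
        log.warning("near-singular kriging system; adding diagonal jitter")
        A[:n, :n] += 1e-10 * np.eye(n) * max(vario.nugget + vario.partial_sill, 1.0)
    return A, n


def ordinary_krige_points(
    samples: Sequence[StationSample],
    vario: SphericalVariogram,
    xs: Sequence[float],
    ys: Sequence[float],
) -> np.ndarray:
    """Ordinary-kriging predictions at arbitrary points; the (n+1)x(n+1)
    system matrix is factorized once and reused for every target."""
    if len(samples) < 3:
        raise ValueError("need at least 3 samples")
    A, n = _ok_matrix(samples, vario)
    sx = np.array([s.x for s in samples])
    sy = np.array([s.y for s in samples])
    v = np.array([s.value for s in samples])
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    d = np.hypot(sx[:, None] - xs[None, :], sy[:, None] - ys[None, :])
    B = np.vstack([variogram_value(vario, d), np.ones(xs.size)])
    lam = np.linalg.solve(A, B)  # (n+1, n_targets)
    return lam[:n].T @ v


def ordinary_krige(
    samples: Sequence[StationSample], vario: SphericalVariogram, spec: GridSpec
) -> RasterLayer:
    """Full-grid ordinary-kriging surface."""
    cx, cy = spec.cell_centers()
    preds = ordinary_krige_points(samples, vario, cx.ravel(), cy.ravel())
    return RasterLayer(spec, "ok", preds.reshape(spec.shape))


def krige_auto(
    samples: Sequence[StationSample], xs: Sequence[float], ys: Sequence[float]
) -> np.ndarray:
    """Fit the spherical variogram from the samples, then predict."""
    vario = fit_spherical(empirical_semivariogram(samples))
    return ordinary_krige_points(samples, vario, xs, ys)


def mars3_design(
    stations: Sequence[StationSample], dem: RasterLayer
) -> np.ndarray:
    """The 3-column MARS3 design: x, y, elevation at the stations."""
    xs = [s.x for s in stations]
    ys = [s.y for s in stations]
    return np.column_stack([xs, ys, sample_many(dem, xs, ys)])


def fit_mars3(
    stations: Sequence[StationSample],
    dem: RasterLayer,
    config: MarsConfig = MarsConfig(),
) -> MarsModel:
    """MARS on latitude/longitude/elevation only — the strongest published
    reference interpolator and the ablation of the 14-covariate stack."""
    y = np.array([s.value for s in stations])
    return fit_mars(mars3_design(stations, dem), y, config)


def mars3_predict_points(
    model: MarsModel, dem: RasterLayer, xs: Sequence[float], ys: Sequence[float]
) -> np.ndarray:
    X = np.column_stack([xs, ys, sample_many(dem, xs, ys)])
    return mars_predict(model, X)
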
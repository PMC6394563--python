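"""Multivariate adaptive regression splines with piecewise-linear hinges.

The model is f(x) = c0 + sum_i c_i B_i(x), each basis function B_i a product
of hinge terms max(0, +/-(x_v - knot)). Fitting is the classic two-phase
procedure:

* **forward pass** — greedily add reflected hinge pairs. At every step each
  existing basis function of degree < max_degree is considered as a parent,
  crossed with every variable it does not already contain and every distinct
  observed value of that variable as a knot; the pair giving the largest SSE
  decrease (all coefficients refitted by least squares) is committed.
* **backward pass** — starting from the deliberately over-fit forward model,
  repeatedly delete the basis function whose removal raises SSE least,
  producing a nested model sequence, and return the member with the lowest
  generalized cross-validation score (GCV).

Only piecewise-linear (not cubic) splines are implemented. There is no
randomness anywhere in the fit: identical data and configuration give
identical models.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

_EPS = 1e-12


@dataclass(frozen=True)
class HingeTerm:
    """One hinge max(0, sign * (x[var_index] - knot))."""

    var_index: int
    sign: int  # +1 or -1
    knot: float

    def __post_init__(self) -> None:
        if self.sign not in (+1, -1):
            raise ValueError("sign must be +1 or -1")
        if self.var_index < 0:
            raise ValueError("var_index must be non-negative")


@dataclass(frozen=True)
class BasisFunction:
    """A product of hinge terms; the empty product is the constant 1."""

    terms: tuple[HingeTerm, ...] = ()

    @property
    def degree(self) -> int:
        return len(self.terms)

    def variables(self) -> set[int]:
        return {t.var_index for t in self.terms}

    def with_term(self, term: HingeTerm) -> "BasisFunction":
        if term.var_index in self.variables():
            raise ValueError("basis function already involves this variable")
        return BasisFunction(self.terms + (term,))


def eval_basis(b: BasisFunction, x: Sequence[float]) -> float:
    """Evaluate one basis function at a single point (>= 0 by construction)."""
    x = np.asarray(x, dtype=float)
    out = 1.0
    for t in b.terms:
        if t.var_index >= x.size:
            raise IndexError(f"var_index {t.var_index} out of range for p={x.size}")
        out *= max(0.0, t.sign * (x[t.var_index] - t.knot))
    return out


def _basis_column(b: BasisFunction, X: np.ndarray) -> np.ndarray:
    col = np.ones(X.shape[0])
    for t in b.terms:
        col *= np.maximum(0.0, t.sign * (X[:, t.var_index] - t.knot))
    return col


@dataclass
class MarsModel:
    """A fitted model: intercept, coefficients, non-constant basis functions
    and the fit diagnostics (SSE, GCV, penalty, training size)."""

    intercept: float
    coefficients: list[float]
    basis: list[BasisFunction]
    gcv: float
    sse: float
    penalty: float
    n_train: int

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.basis):
            raise ValueError("one coefficient per basis function")

    @property
    def n_basis(self) -> int:
        """Number of basis functions counting the intercept (the m of GCV)."""
        return 1 + len(self.basis)


def eval_model(model: MarsModel, x: Sequence[float]) -> float:
    """f(x) = c0 + sum c_i B_i(x) at a single point."""
    return model.intercept + sum(
        c * eval_basis(b, x) for c, b in zip(model.coefficients, model.basis)
    )


def predict(model: MarsModel, X: np.ndarray) -> np.ndarray:
    """Vectorized model evaluation over the rows of X (n x p)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.full(X.shape[0], model.intercept)
    for c, b in zip(model.coefficients, model.basis):
        out += c * _basis_column(b, X)
    return out


def gcv(sse: float, n: int, m: int, d: float) -> float:
    """GCV = (SSE/n) / (1 - C(m)/n)^2 with effective parameter count
    C(m) = m + d (m - 1) / 2; m counts the intercept. Returns ``inf`` when
    the effective parameters reach n (infinitely complex model)."""
    if n <= 0 or m < 1:
        raise ValueError("need n > 0 and m >= 1")
    c_eff = m + d * (m - 1) / 2.0
    denom = 1.0 - c_eff / n
    if denom <= 0:
        return float("inf")
    return (sse / n) / denom**2


@dataclass(frozen=True)
class MarsConfig:
    """Fitting knobs. ``max_terms`` limits basis functions including the
    intercept (default min(21, n-1), keeping the design overdetermined at
    the ~21-station scale); ``max_degree`` 2 allows two-way hinge
    interactions; ``penalty`` is the GCV d (3 is standard practice for
    interaction models); ``endspan`` demands at least that many
    parent-support observations strictly on each side of a candidate knot,
    so no hinge is fitted on a sliver of one or two edge points (such
    hinges earn enormous coefficients and extrapolate wildly at prediction
    time)."""

    max_terms: int | None = None
    max_degree: int = 2
    penalty: float = 3.0
    endspan: int | None = None

    def resolve_endspan(self, n_support: int, p: int) -> int:
        """Friedman's endspan: about 3 - log2(alpha/p) observations (alpha
        0.05) must lie strictly on each side of a knot, capped so at least
        one interior knot stays eligible. Guards against hinges fitted on
        one or two edge points, whose coefficients explode."""
        if self.endspan is not None:
            return self.endspan
        le = int(np.ceil(3.0 - np.log2(0.05 / max(p, 1))))
        return max(2, min(le, (n_support - 1) // 2))

    def resolve_max_terms(self, n: int) -> int:
        if self.max_terms is not None:
            if self.max_terms < 2:
                raise ValueError("max_terms must be >= 2")
            return self.max_terms
        return max(2, min(21, n - 1))


def _lstsq_fit(B: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    resid = y - B @ coef
    return coef, float(resid @ resid)


def forward_pass(
    X: np.ndarray, y: np.ndarray, config: MarsConfig = MarsConfig()
) -> MarsModel:
    """Greedy basis construction minimizing training SSE.

    Candidate scoring uses the Schur complement against the current design:
    for a parent column b_p and hinge pair (h+, h-), the SSE drop of adding
    both columns is computed for every knot of a (parent, variable) block in
    one vectorized sweep; the committed model is then refit from scratch by
    least squares so coefficients always solve the full normal equations.
    The returned model is deliberately over-fit; ties in SSE break toward
    the earlier parent, smaller variable index, then smaller knot.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y must be a length-n vector")
    if config.max_degree < 1:
        raise ValueError("max_degree must be >= 1")
    max_terms = config.resolve_max_terms(n)

    basis: list[BasisFunction] = [BasisFunction()]
    B = np.ones((n, 1))
    coef, sse = _lstsq_fit(B, y)
    y_scale = float(np.sum((y - y.mean()) ** 2)) + _EPS

    while B.shape[1] + 2 <= max_terms and sse > _EPS * y_scale:
        resid = y - B @ coef
        G = B.T @ B
        # tiny ridge keeps the Schur scoring stable if B is near-singular;
        # the committed fit below never uses it
        G_reg = G + _EPS * np.trace(G) * np.eye(G.shape[0])
        best = None  # (gain, parent_idx, var, knot)
        for pi, parent in enumerate(basis):
            if parent.degree >= config.max_degree:
                continue
            bp = B[:, pi]
            used = parent.variables()
            support = np.abs(bp) > _EPS
            for v in range(p):
                if v in used:
                    continue
                xv_sup = np.sort(X[support, v])
                knots = np.unique(X[:, v])
                endspan = config.resolve_endspan(int(support.sum()), p)
                if endspan > 0:
                    # keep knots with >= endspan support points strictly on
                    # each side, so both reflected hinges rest on real data
                    lo_count = np.searchsorted(xv_sup, knots, side="left")
                    hi_count = xv_sup.size - np.searchsorted(xv_sup, knots, side="right")
                    knots = knots[(lo_count >= endspan) & (hi_count >= endspan)]
                if knots.size == 0:
                    continue
                hp = np.maximum(0.0, X[:, v][:, None] - knots[None, :]) * bp[:, None]
                hm = np.maximum(0.0, knots[None, :] - X[:, v][:, None]) * bp[:, None]
                gains = _pair_gains(G_reg, B, resid, hp, hm)
                k = int(np.argmax(gains))
                if gains[k] > _EPS * y_scale and (
                    best is None or gains[k] > best[0] * (1 + 1e-9)
                ):
                    best = (float(gains[k]), pi, v, float(knots[k]))
        if best is None:
            break
        gain, pi, v, knot = best
        if gain < 1e-6 * sse:
            break
        parent = basis[pi]
        new_cols, new_bfs = [], []
        B_aug = B
        for sign in (+1, -1):
            bf = parent.with_term(HingeTerm(v, sign, knot))
            col = _basis_column(bf, X)
            # drop columns (numerically) inside the current column span:
            # reflected pairs on one variable overlap linearly, and a
            # dependent column would make the design rank-deficient
            proj, *_ = np.linalg.lstsq(B_aug, col, rcond=None)
            res = col - B_aug @ proj
            if np.linalg.norm(res) > 1e-7 * max(np.linalg.norm(col), 1.0):
                new_cols.append(col)
                new_bfs.append(bf)
                B_aug = np.column_stack([B_aug, col])
        if not new_cols:
            break
        B_new = np.column_stack([B] + new_cols)
        coef_new, sse_new = _lstsq_fit(B_new, y)
        if sse - sse_new < 1e-6 * sse:
            break
        basis = basis + new_bfs
        B, coef, sse = B_new, coef_new, sse_new

    return _to_model(basis, coef, sse, n, config)


def _pair_gains(
    G_reg: np.ndarray,
    B: np.ndarray,
    resid: np.ndarray,
    hp: np.ndarray,
    hm: np.ndarray,
) -> np.ndarray:
    """SSE decrease from appending each reflected hinge-column pair.

    The two hinge columns of one knot have pointwise-disjoint support, so
    their raw inner product vanishes; all remaining 2x2 Schur algebra is
    vectorized across knots.
    """
    Up = np.linalg.solve(G_reg, B.T @ hp)  # (m, K)
    Um = np.linalg.solve(G_reg, B.T @ hm)
    BtHp = B.T @ hp
    BtHm = B.T @ hm
    App = (hp * hp).sum(axis=0) - (BtHp * Up).sum(axis=0)
    Amm = (hm * hm).sum(axis=0) - (BtHm * Um).sum(axis=0)
    Apm = -(BtHp * Um).sum(axis=0)
    bp = resid @ hp
    bm = resid @ hm
    scale = np.maximum(np.maximum(App, Amm), 1.0)
    tol = 1e-10 * scale
    App_ok = App > tol
    Amm_ok = Amm > tol
    det = App * Amm - Apm**2
    det_ok = App_ok & Amm_ok & (det > tol * scale)
    gains = np.zeros(hp.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        g2 = (Amm * bp**2 - 2 * Apm * bp * bm + App * bm**2) / det
        gp = bp**2 / App
        gm = bm**2 / Amm
    gains[det_ok] = g2[det_ok]
    only_p = App_ok & ~det_ok
    gains[only_p] = np.maximum(gains[only_p], gp[only_p])
    only_m = Amm_ok & ~det_ok
    gains[only_m] = np.maximum(gains[only_m], gm[only_m])
    return np.maximum(gains, 0.0)


def _to_model(
    basis: list[BasisFunction],
    coef: np.ndarray,
    sse: float,
    n: int,
    config: MarsConfig,
) -> MarsModel:
    return MarsModel(
        intercept=float(coef[0]),
        coefficients=[float(c) for c in coef[1:]],
        basis=list(basis[1:]),
        gcv=gcv(sse, n, len(basis), config.penalty),
        sse=sse,
        penalty=config.penalty,
        n_train=n,
    )


def backward_pass(
    model: MarsModel, X: np.ndarray, y: np.ndarray, config: MarsConfig | None = None
) -> MarsModel:
    """GCV-guided pruning of a forward-pass model.

    Deletes, one at a time, the basis function whose removal raises SSE
    least (coefficients refitted at every step), yielding the nested
    sequence down to the intercept-only model, and returns the sequence
    member with the lowest GCV (the largest such model on exact ties, so a
    GCV-optimal input is returned unchanged).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    d = config.penalty if config is not None else model.penalty
    cfg = config or MarsConfig(penalty=model.penalty)

    current = list(model.basis)
    candidates: list[tuple[float, list[BasisFunction], np.ndarray, float]] = []

    def refit(bfs: list[BasisFunction]) -> tuple[np.ndarray, float]:
        B = np.column_stack(
            [np.ones(n)] + [_basis_column(b, X) for b in bfs]
        )
        return _lstsq_fit(B, y)

    coef, sse = refit(current)
    candidates.append((gcv(sse, n, 1 + len(current), d), current, coef, sse))
    while current:
        best_i, best_fit = None, None
        for i in range(len(current)):
            trial = current[:i] + current[i + 1 :]
            coef_t, sse_t = refit(trial)
            if best_fit is None or sse_t < best_fit[1]:
                best_i, best_fit = i, (coef_t, sse_t)
        current = current[:best_i] + current[best_i + 1 :]
        coef, sse = best_fit
        candidates.append((gcv(sse, n, 1 + len(current), d), current, coef, sse))

    gcvs = np.array([c[0] for c in candidates])
    g, bfs, coef, sse = candidates[int(np.argmin(gcvs))]
    return MarsModel(
        intercept=float(coef[0]),
        coefficients=[float(c) for c in coef[1:]],
        basis=list(bfs),
        gcv=float(g),
        sse=float(sse),
        penalty=d,
        n_train=n,
    )


def fit_mars(
    X: np.ndarray, y: np.ndarray, config: MarsConfig = MarsConfig()
) -> MarsModel:
    """Forward knot search followed by GCV backward pruning."""
    fwd = forward_pass(X, y, config)
    return backward_pass(fwd, X, y, config)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def model_to_dict(model: MarsModel) -> dict:
    return {
        "intercept": model.intercept,
        "coefficients": model.coefficients,
        "basis": [
            [
                {"var_index": t.var_index, "sign": t.sign, "knot": t.knot}
                for t in b.terms
            ]
            for b in model.basis
        ],
        "gcv": model.gcv,
        "sse": model.sse,
        "penalty": model.penalty,
        "n_train": model.n_train,
    }


def model_from_dict(doc: dict) -> MarsModel:
    basis = [
        BasisFunction(
            tuple(
                HingeTerm(int(t["var_index"]), int(t["sign"]), float(t["knot"]))
                for t in terms
            )
        )
        for terms in doc["basis"]
    ]
    return MarsModel(
        intercept=float(doc["intercept"]),
        coefficients=[float(c) for c in doc["coefficients"]],
        basis=basis,
        gcv=float(doc.get("gcv", 0.0)),
        sse=float(doc.get("sse", 0.0)),
        penalty=float(doc.get("penalty", 3.0)),
        n_train=int(doc.get("n_train", 0)),
    )


def save_model(model: MarsModel, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1)


def load_model(path: str | os.PathLike) -> MarsModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))


def reference_no2_model() -> MarsModel:
    """The published two-component NO2 interpolation model for Tehran that
    this package's evaluator must reproduce: four hinge basis functions over
    the first two principal-component scores (x1, x2), shipped as a JSON
    fixture and used in tests and the acceptance check."""
    doc = json.loads(
        resources.files("pcamars.data").joinpath("reference_no2_model.json").read_text()
    )
    return model_from_dict(doc)
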
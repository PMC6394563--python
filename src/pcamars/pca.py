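"""Principal component analysis by eigen-decomposition of the sample
covariance matrix.

The covariate stack is already min-max scaled to [0, 1], so the covariance
(not correlation) matrix is decomposed. Eigenvectors are the rows of the
orthogonal transform P, ordered by decreasing eigenvalue, with the sign
convention that each eigenvector's largest-magnitude element is positive
(the sign of an eigenvector is otherwise arbitrary, and a fixed convention
makes fits reproducible bit-for-bit).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class PcaTransform:
    """Fitted PCA: column means, eigenvector rows P, eigenvalues, and the
    number of leading components kept at transform time."""

    means: np.ndarray  # (p,)
    components: np.ndarray  # (p, p), rows are eigenvectors
    eigenvalues: np.ndarray  # (p,), descending, >= 0
    n_keep: int

    @property
    def explained_ratio(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total

    @property
    def p(self) -> int:
        return self.means.size


def fit_pca(X: np.ndarray) -> PcaTransform:
    """Eigen-decompose the sample covariance of mean-centred X (n x p).

    Zero eigenvalues of rank-deficient input are retained (clipped at 0,
    never dropped), so the explained-variance ratios always sum to 1 over
    all p components.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than variables ({p})")
    if not np.isfinite(X).all():
        raise ValueError("X must be finite")
    means = X.mean(axis=0)
    cov = np.cov(X - means, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    P = evecs[:, order].T  # rows = eigenvectors
    # sign convention: largest-|.| element of each eigenvector positive
    for i in range(p):
        j = int(np.argmax(np.abs(P[i])))
        if P[i, j] < 0:
            P[i] = -P[i]
    return PcaTransform(means=means, components=P, eigenvalues=evals, n_keep=p)


def transform(t: PcaTransform, X: np.ndarray) -> np.ndarray:
    """Scores of X on the first ``n_keep`` components: (X - mean) @ P.T."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != t.p:
        raise ValueError(f"X has {X.shape[1]} columns, transform expects {t.p}")
    return (X - t.means) @ t.components[: t.n_keep].T


def inverse_transform(t: PcaTransform, Y: np.ndarray) -> np.ndarray:
    """Back-project scores into the original variable space."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    return Y @ t.components[: t.n_keep] + t.means


def select_components(
    t: PcaTransform, k: int | None = None, variance_threshold: float | None = None
) -> PcaTransform:
    """Keep the first k components, or the smallest k whose cumulative
    explained-variance ratio reaches ``variance_threshold``. Default k=3."""
    if k is not None and variance_threshold is not None:
        raise ValueError("give either k or variance_threshold, not both")
    if variance_threshold is not None:
        if not 0 < variance_threshold <= 1:
            raise ValueError("variance_threshold must be in (0, 1]")
        cum = np.cumsum(t.explained_ratio)
        k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
        k = min(k, t.p)
    if k is None:
        k = 3
    if not 1 <= k <= t.p:
        raise ValueError(f"k must be in [1, {t.p}], got {k}")
    return replace(t, n_keep=k)


def save_pca(t: PcaTransform, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "means": t.means.tolist(),
                "components": t.components.tolist(),
                "eigenvalues": t.eigenvalues.tolist(),
                "n_keep": t.n_keep,
            },
            fh,
        )


def load_pca(path: str | os.PathLike) -> PcaTransform:
    with open(path) as fh:
        doc = json.load(fh)
    return PcaTransform(
        means=np.array(doc["means"], dtype=float),
        components=np.array(doc["components"], dtype=float),
        eigenvalues=np.array(doc["eigenvalues"], dtype=float),
        n_keep=int(doc["n_keep"]),
    )
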
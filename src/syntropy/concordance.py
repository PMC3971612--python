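"""Global microbiome-metabolome concordance: PCA, Procrustes, co-inertia RV.

Both tests ask the same question from different angles: do two multivariate
tables measured on the same samples share structure? Procrustes superimposes
two ordinations (translation, uniform scaling, rotation) and reports the
residual m12^2; co-inertia reports the RV matrix correlation. Significance in
both comes from permuting the sample rows of one table.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import get_rng, logger


@dataclass
class Ordination:
    """Sample scores on successive principal axes, with their eigenvalues."""

    scores: pd.DataFrame
    eigenvalues: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


@dataclass
class ConcordanceResult:
    statistic: float  # Procrustes m12^2 or RV
    p_value: float
    n_permutations: int
    per_feature_weights: pd.DataFrame | None = None
    statistic_name: str = ""


def pca_euclidean(x: pd.DataFrame, n_axes: int = 2) -> Ordination:
    """Principal components of column-centered data.

    Equivalent to classical (metric) scaling of Euclidean distances between
    samples; deterministic up to axis sign.
    """
    if x.shape[0] < 3:
        raise ValueError("need >= 3 samples for PCA")
    v = x.to_numpy(float)
    v = v - v.mean(axis=0)
    u, s, _ = np.linalg.svd(v, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if n_axes > rank:
        logger.warning("pca_euclidean: requested %d axes but rank is %d; truncating", n_axes, rank)
        n_axes = rank
    scores = u[:, :n_axes] * s[:n_axes]
    eig = (s ** 2) / (v.shape[0] - 1)
    return Ordination(
        pd.DataFrame(scores, index=x.index, columns=[f"PC{i+1}" for i in range(n_axes)]),
        eig[:n_axes],
    )


def _procrustes_congruence(xa: np.ndarray, xb: np.ndarray) -> float:
    """Sum of singular values of the cross-product of two unit-SS centered
    configurations; 1 - (this)^2 is the symmetric Procrustes m12^2."""
    s = np.linalg.svd(xa.T @ xb, compute_uv=False)
    return float(s.sum())


def _center_scale(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0)
    ss = np.sqrt((x ** 2).sum())
    if ss == 0:
        raise ValueError("configuration has zero variance")
    return x / ss


def procrustes_test(a: Ordination, b: Ordination, n_perm: int = 999, seed=None) -> ConcordanceResult:
    """Symmetric Procrustes superimposition with a permutation test.

    m12^2 = 1 - (sum of singular values of the cross-product)^2 after both
    configurations are centered and scaled to unit sum of squares. The p-value
    permutes the sample rows of the second configuration:
    p = (1 + #{congruence_perm >= congruence_obs}) / (1 + n_perm).
    """
    if list(a.scores.index) != list(b.scores.index):
        raise ValueError("ordinations must share the same samples in the same order")
    if a.n_axes != b.n_axes:
        raise ValueError("ordinations must have the same number of axes")
    xa = _center_scale(a.scores.to_numpy(float))
    xb = _center_scale(b.scores.to_numpy(float))
    obs = _procrustes_congruence(xa, xb)
    rng = get_rng(seed)
    n = xa.shape[0]
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    # batched SVDs over all permuted cross-products
    cross = np.einsum("pni,nj->pij", xa[perms].transpose(0, 1, 2), xb)
    sv = np.linalg.svd(cross, compute_uv=False)
    hits = int((sv.sum(axis=1) >= obs - 1e-12).sum())
    p = (1 + hits) / (1 + n_perm)
    return ConcordanceResult(statistic=max(0.0, 1.0 - obs ** 2), p_value=p,
                             n_permutations=n_perm, statistic_name="m12_squared")


def rv_coefficient(x: np.ndarray, y: np.ndarray) -> float:
    """RV = trace(X'Y Y'X) / sqrt(trace((X'X)^2) trace((Y'Y)^2)) on centered tables."""
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    num = (np.linalg.norm(x.T @ y, "fro")) ** 2
    dx = (np.linalg.norm(x.T @ x, "fro")) ** 2
    dy = (np.linalg.norm(y.T @ y, "fro")) ** 2
    if dx == 0 or dy == 0:
        raise ValueError("zero-variance table")
    return float(num / np.sqrt(dx * dy))


def coinertia_rv(x: pd.DataFrame, y: pd.DataFrame, n_perm: int = 999, seed=None,
                 n_axes: int = 2, reduce_with_pca: bool = False) -> ConcordanceResult:
    """Co-inertia RV coefficient with a Monte Carlo row-permutation test.

    ``per_feature_weights`` carries each feature's loading norm on the first
    co-inertia axes (the covariance-strength ranking of features); set
    ``reduce_with_pca`` to run the test on PCA-reduced score matrices instead
    of the raw centered tables.
    """
    if list(x.index) != list(y.index):
        raise ValueError("tables must share the same samples in the same order")
    if reduce_with_pca:
        x = pca_euclidean(x, n_axes=min(x.shape) - 1).scores
        y = pca_euclidean(y, n_axes=min(y.shape) - 1).scores
    xv = x.to_numpy(float)
    yv = y.to_numpy(float)
    obs = rv_coefficient(xv, yv)
    rng = get_rng(seed)
    n = xv.shape[0]
    xc = xv - xv.mean(axis=0)
    yc = yv - yv.mean(axis=0)
    dx = np.linalg.norm(xc.T @ xc, "fro") ** 2
    dy = np.linalg.norm(yc.T @ yc, "fro") ** 2
    denom = np.sqrt(dx * dy)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xp = xc[perm]
        xp = xp - xp.mean(axis=0)
        num = np.linalg.norm(xp.T @ yc, "fro") ** 2
        if num / denom >= obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_perm)

    u, s, vt = np.linalg.svd(xc.T @ yc, full_matrices=False)
    k = min(n_axes, s.size)
    wx = np.sqrt(((u[:, :k] * s[:k]) ** 2).sum(axis=1))
    wy = np.sqrt(((vt[:k].T * s[:k]) ** 2).sum(axis=1))
    weights = pd.concat([
        pd.DataFrame({"feature_id": x.columns, "table": "x", "weight": wx}),
        pd.DataFrame({"feature_id": y.columns, "table": "y", "weight": wy}),
    ], ignore_index=True)
    return ConcordanceResult(statistic=obs, p_value=p, n_permutations=n_perm,
                             per_feature_weights=weights, statistic_name="RV")
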
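"""Pairwise eQTL sharing, correlation distances, and non-metric MDS.

Two effects are shared when they have the same sign and their magnitudes
differ by at most a factor of two.  The sharing matrix reports, per dataset
pair, the fraction of shared lead signals among eligible ones; with the
default denominator a signal is eligible when it is non-missing
(pre-substitution) in at least one of the two datasets, so zero-substituted
entries count as non-shared.  Non-metric MDS follows Kruskal: monotone
(isotonic) regression of configuration distances onto dissimilarity ranks
and minimization of stress-1, here via SMACOF majorization initialized from
classical (Torgerson) scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression

from .harmonize import EffectMatrix


@dataclass
class SharingMatrix:
    """Symmetric dataset x dataset sharing fractions in [0, 1], diagonal 1."""

    values: pd.DataFrame
    denominator_policy: str = "any"

    @property
    def datasets(self) -> list[str]:
        return list(self.values.index)


@dataclass
class MdsEmbedding:
    """2-D (by default) embedding with its final Kruskal stress-1."""

    coordinates: pd.DataFrame
    stress: float
    k: int = 2
    n_iter: int = 0
    stress_history: list[float] = field(default_factory=list)


def pair_shared(beta_a: float, beta_b: float) -> bool:
    """Same sign and magnitudes within a factor of two (inclusive); zeros never share."""
    if not (np.isfinite(beta_a) and np.isfinite(beta_b)):
        raise ValueError("effect sizes must be finite")
    if beta_a == 0 or beta_b == 0 or np.sign(beta_a) != np.sign(beta_b):
        return False
    hi = max(abs(beta_a), abs(beta_b))
    lo = min(abs(beta_a), abs(beta_b))
    return hi / lo <= 2.0


def _pair_shared_vec(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        same_sign = (np.sign(a) == np.sign(b)) & (a != 0) & (b != 0)
        hi = np.maximum(np.abs(a), np.abs(b))
        lo = np.minimum(np.abs(a), np.abs(b))
        ratio_ok = np.where(lo > 0, hi / np.where(lo > 0, lo, 1.0) <= 2.0, False)
    return same_sign & ratio_ok


def sharing_matrix(effects: EffectMatrix, policy: str = "any") -> SharingMatrix:
    """Pairwise sharing fractions from a (substituted) effect matrix.

    ``policy`` selects the denominator: ``any`` counts signals non-missing in
    at least one of the two datasets (missing entries, substituted to zero,
    then count as non-shared); ``both`` restricts to signals measured in
    both.  Pairs with no eligible signal get NaN with a warning.
    """
    if policy not in {"any", "both"}:
        raise ValueError(f"unknown denominator policy {policy!r}")
    datasets = list(effects.beta.columns)
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets")
    beta = effects.beta.to_numpy(dtype=float)
    beta = np.where(np.isnan(beta), 0.0, beta)  # explicit-missing -> zero substitution
    present = ~effects.missing.to_numpy(dtype=bool)
    m = len(datasets)
    out = np.full((m, m), np.nan)
    np.fill_diagonal(out, 1.0)
    for i in range(m):
        for j in range(i + 1, m):
            if policy == "any":
                eligible = present[:, i] | present[:, j]
            else:
                eligible = present[:, i] & present[:, j]
            n_eligible = int(eligible.sum())
            if n_eligible == 0:
                warnings.warn(f"no eligible signals for pair ({datasets[i]}, {datasets[j]})")
                continue
            shared = _pair_shared_vec(beta[eligible, i], beta[eligible, j])
            out[i, j] = out[j, i] = shared.sum() / n_eligible
    return SharingMatrix(
        values=pd.DataFrame(out, index=datasets, columns=datasets),
        denominator_policy=policy,
    )


def correlation_distance(profiles: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Distance matrix D = 1 - correlation between the rows (datasets).

    ``profiles`` is dataset x feature; ``method`` is pearson or spearman.
    """
    if method not in {"pearson", "spearman"}:
        raise ValueError(f"unknown method {method!r}")
    x = profiles.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 features")
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = list(profiles.index[sd == 0])
        raise ValueError(f"zero-variance profile(s): {bad}")
    if method == "spearman":
        x = np.apply_along_axis(rankdata, 1, x)
    r = np.corrcoef(x)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson scaling: double-centered squared distances, top-k eigenvectors."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals_k = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals_k)


def _kruskal_stress(d_config: np.ndarray, disparities: np.ndarray) -> float:
    denom = float(np.sum(d_config**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d_config - disparities) ** 2) / denom))


def nonmetric_mds(
    D: pd.DataFrame | np.ndarray,
    k: int = 2,
    init: str | np.ndarray = "classical",
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int | None = None,
) -> MdsEmbedding:
    """Kruskal non-metric MDS minimizing stress-1.

    Each iteration fits disparities by pool-adjacent-violators isotonic
    regression of configuration distances on the dissimilarity order (ties
    handled by the primary approach: tied blocks are pre-sorted by current
    distance so they do not constrain each other), then updates the
    configuration with a Guttman transform.  Iteration stops when stress
    stops decreasing; the recorded stress history is non-increasing.  An
    all-zero dissimilarity matrix returns the zero embedding with stress 0.
    """
    if isinstance(D, pd.DataFrame):
        index = D.index
        d = D.to_numpy(dtype=float)
    else:
        d = np.asarray(D, dtype=float)
        index = pd.RangeIndex(d.shape[0])
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("D must be a symmetric square matrix")
    if np.any(d < -1e-12):
        raise ValueError("D must be non-negative")
    n = d.shape[0]
    delta = squareform(d, checks=False)
    if np.all(delta == 0):
        coords = pd.DataFrame(np.zeros((n, k)), index=index,
                              columns=[f"dim{i + 1}" for i in range(k)])
        return MdsEmbedding(coordinates=coords, stress=0.0, k=k, n_iter=0,
                            stress_history=[0.0])

    if isinstance(init, np.ndarray):
        x = np.array(init, dtype=float)
    elif init == "classical":
        x = _classical_mds(d, k)
        if not np.any(x):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal((n, k)) * 1e-3
    else:
        raise ValueError(f"unknown init {init!r}")

    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    best_x = x
    history: list[float] = []
    n_iter = 0
    for it in range(max_iter):
        dist = pdist(x)
        order = np.lexsort((dist, delta))  # primary tie approach
        fitted = iso.fit_transform(np.arange(len(delta)), dist[order])
        disparities = np.empty_like(fitted)
        disparities[order] = fitted
        stress = _kruskal_stress(dist, disparities)
        if history and stress > history[-1]:
            break
        history.append(stress)
        best_x = x
        n_iter = it + 1
        if stress == 0 or (len(history) > 1 and history[-2] - stress < tol):
            break
        # Guttman transform
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(dist > 0, disparities / dist, 0.0)
        b = -squareform(ratio)
        np.fill_diagonal(b, -b.sum(axis=1))
        x = b @ x / n
    coords = pd.DataFrame(best_x, index=index, columns=[f"dim{i + 1}" for i in range(k)])
    return MdsEmbedding(
        coordinates=coords, stress=history[-1] if history else 0.0, k=k,
        n_iter=n_iter, stress_history=history,
    )
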
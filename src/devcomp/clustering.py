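"""Fuzzy c-means clustering of stage-series expression profiles.

Profiles are z-scored per gene and clustered with standard fuzzy c-means
(membership update proportional to ``distance ** (-2 / (m - 1))``,
centroids as ``membership ** m``-weighted means). The cluster number is
chosen by an explicit elbow rule on the minimum pairwise centroid
distance as a function of k.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

from devcomp.expression import ExpressionMatrix, average_replicates, zscore_rows

logger = logging.getLogger(__name__)

_ZERO_DIST = 1e-12


@dataclass
class ClusterModel:
    """Fitted fuzzy c-means model.

    ``membership`` rows sum to 1; ``assignments`` is the argmax of the
    membership row (ties to the lowest cluster index). Cluster labels are
    integers ``1..k`` to match the usual presentation of stage-series
    clusters.
    """

    k: int
    m: float
    centroids: pd.DataFrame  # k x n_stages, index = cluster labels 1..k
    membership: pd.DataFrame  # genes x k
    assignments: pd.Series  # gene -> cluster label
    objective: float
    seed: int
    n_iter: int
    converged: bool
    objective_trace: list[float] | None = None

    def __post_init__(self) -> None:
        rows = self.membership.to_numpy().sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("membership rows must sum to 1")
        if not np.isfinite(self.centroids.to_numpy()).all():
            raise ValueError("centroids must be finite")


def estimate_fuzzifier(n_genes: int, n_stages: int) -> float:
    """Empirical fuzzifier from data dimensionality.

    Uses the published empirical relation between the fuzzifier, the
    number of profiles N and their dimension D that is standard practice
    for soft clustering of expression time courses:

    ``m = 1 + (1418/N + 22.05) * D**-2
         + (12.33/N + 0.243) * D**(-0.0406 ln N - 0.1134)``
    """
    n, d = float(n_genes), float(n_stages)
    if n < 2 or d < 2:
        return 2.0
    return float(
        1.0
        + (1418.0 / n + 22.05) * d ** -2.0
        + (12.33 / n + 0.243) * d ** (-0.0406 * np.log(n) - 0.1134)
    )


def standardize_profiles(
    m: ExpressionMatrix,
    drop_unexpressed: bool = True,
    expressed_threshold: float = 2.0,
) -> ExpressionMatrix:
    """Average replicates, drop unexpressed genes and z-score each row.

    A gene is kept when its maximum per-stage value is strictly above
    ``expressed_threshold`` (set 0 to drop only all-zero profiles).
    Zero-variance rows cannot be z-scored and are removed with a logged
    count. Output layer is ``zscore``.
    """
    if m.layer not in ("tpm", "normalized_counts"):
        raise ValueError(
            f"standardize_profiles expects layer 'tpm' or 'normalized_counts', got {m.layer!r}"
        )
    if m.replicate_map is not None:
        m = average_replicates(m)
    data = m.data
    if drop_unexpressed:
        keep = (data.to_numpy() > expressed_threshold).any(axis=1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info(
                "discarded %d of %d genes not expressed at any stage",
                n_dropped,
                data.shape[0],
            )
        data = data.loc[keep]
    z, _ = zscore_rows(data, drop_constant=True)
    if z.shape[0] == 0:
        raise ValueError("all genes removed during standardization")
    return m.with_layer(z, "zscore")


def _fcm_once(
    x: np.ndarray,
    k: int,
    m: float,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, int, bool, list[float]]:
    """One fuzzy c-means run from a random initialization."""
    n = x.shape[0]
    centroids = x[rng.choice(n, size=k, replace=False)].astype(float).copy()
    exponent = -2.0 / (m - 1.0)
    u = np.full((n, k), 1.0 / k)
    converged = False
    trace: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        d = cdist(x, centroids)
        zero = d < _ZERO_DIST
        with np.errstate(divide="ignore", invalid="ignore"):
            w = d**exponent
            u = w / w.sum(axis=1, keepdims=True)
        # points coinciding with a centroid get full membership there
        hit = zero.any(axis=1)
        if hit.any():
            u[hit] = 0.0
            first = zero[hit].argmax(axis=1)
            u[np.flatnonzero(hit), first] = 1.0
        um = u**m
        denom = um.sum(axis=0)
        # an empty cluster keeps its centroid
        new_centroids = np.where(
            denom[:, None] > 0, (um.T @ x) / np.maximum(denom, _ZERO_DIST)[:, None], centroids
        )
        shift = np.linalg.norm(new_centroids - centroids, axis=1).max()
        centroids = new_centroids
        trace.append(float((u**m * cdist(x, centroids) ** 2).sum()))
        if shift < tol:
            converged = True
            break
    d = cdist(x, centroids)
    objective = float((u**m * d**2).sum())
    return centroids, u, objective, it, converged, trace


def fuzzy_cmeans(
    z: ExpressionMatrix,
    k: int,
    m: float | None = None,
    seed: int = 0,
    restarts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> ClusterModel:
    """Fit fuzzy c-means on z-scored profiles; best of ``restarts`` runs.

    Deterministic given ``seed`` (single-threaded). Non-convergence of
    the best run raises a warning but still returns the best state.
    """
    if m is None:
        m = estimate_fuzzifier(z.n_genes, z.data.shape[1])
        logger.info("estimated fuzzifier m=%.4f", m)
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if k < 1:
        raise ValueError("k must be >= 1")
    x = z.data.to_numpy(dtype=float)
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds the number of genes ({x.shape[0]})")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, restarts)):
        result = _fcm_once(x, k, m, rng, tol, max_iter)
        if best is None or result[2] < best[2]:
            best = result
    centroids, u, objective, n_iter, converged, trace = best
    if not converged:
        warnings.warn(
            f"fuzzy c-means did not converge within {n_iter} iterations; "
            "returning best state",
            RuntimeWarning,
            stacklevel=2,
        )
    labels = list(range(1, k + 1))
    membership = pd.DataFrame(u, index=z.data.index, columns=labels)
    assignments = pd.Series(
        np.asarray(labels)[u.argmax(axis=1)], index=z.data.index, name="cluster"
    )
    return ClusterModel(
        k=k,
        m=float(m),
        centroids=pd.DataFrame(centroids, index=labels, columns=z.data.columns),
        membership=membership,
        assignments=assignments,
        objective=objective,
        seed=seed,
        n_iter=n_iter,
        converged=converged,
        objective_trace=trace,
    )


def min_centroid_distance(
    z: ExpressionMatrix,
    k_range,
    m: float | None = None,
    seed: int = 0,
    restarts: int = 5,
) -> list[tuple[int, float]]:
    """Minimum pairwise centroid distance for each k in ``k_range``."""
    out = []
    for k in k_range:
        if not 2 <= k <= z.n_genes:
            raise ValueError(f"k={k} outside [2, n_genes]")
        model = fuzzy_cmeans(z, k=k, m=m, seed=seed, restarts=restarts)
        d_min = float(pdist(model.centroids.to_numpy()).min())
        if d_min < 1e-8:
            logger.warning("k=%d produced near-duplicate centroids (d_min=%.2e)", k, d_min)
        out.append((k, d_min))
    return out


def select_k_elbow(series: list[tuple[int, float]]) -> int:
    """Elbow k from a (k, d_min) series.

    Returns the k maximizing the forward discrete second difference
    ``d(k) - 2 d(k+1) + d(k+2)``, i.e. the last point before the sharpest
    curvature drop; ties break to the smallest k. With a purely linear
    decay every second difference is 0 and the smallest evaluable k is
    returned (degenerate: no elbow exists).
    """
    if len(series) < 3:
        raise ValueError("elbow selection needs at least 3 (k, d_min) points")
    ks = [k for k, _ in series]
    if any(b <= a for a, b in zip(ks, ks[1:])):
        raise ValueError("k values must be strictly increasing")
    d = np.asarray([v for _, v in series], dtype=float)
    second = d[:-2] - 2.0 * d[1:-1] + d[2:]
    return ks[int(np.argmax(second))]


def harden_assignments(
    model: ClusterModel, min_membership: float | None = None
) -> pd.Series:
    """Argmax cluster per gene; ties break to the lowest cluster index.

    With ``min_membership`` set, genes whose top membership falls below
    the cutoff are excluded (count logged).
    """
    u = model.membership.to_numpy()
    idx = u.argmax(axis=1)
    labels = model.membership.columns.to_numpy()[idx]
    assignments = pd.Series(labels, index=model.membership.index, name="cluster")
    if min_membership is not None:
        top = u.max(axis=1)
        keep = top >= min_membership
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info(
                "excluded %d genes below minimum membership %.3f",
                n_dropped,
                min_membership,
            )
        assignments = assignments[keep]
    return assignments
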
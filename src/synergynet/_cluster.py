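"""Low-level clustering primitives for expression-state discretization.

Two routines back the mutual-information estimator:

``optimal_1d_labels``
    Exact minimum within-cluster-variance partition of a 1-D sample into at
    most ``k`` contiguous bins, by dynamic programming over the sorted
    values (the 1-D k-means optimum).  Deterministic; no RNG involved.

``batched_kmeans``
    Lloyd's algorithm run simultaneously over a batch of small point sets
    (one per gene pair), with multiple seeded random restarts.  All pairs in
    a scan are clustered in a handful of vectorised numpy passes, which is
    what makes permutation analyses over thousands of pairs tractable.
"""

from __future__ import annotations

import numpy as np

__all__ = ["optimal_1d_labels", "batched_kmeans"]


def optimal_1d_labels(x: np.ndarray, k: int) -> np.ndarray:
    """Optimal partition of ``x`` into at most ``k`` variance-minimising bins.

    Returns integer labels in ``0..k'-1`` (``k' <= k``), ordered by bin
    location, so equal inputs always share a label.  Collapses to fewer
    bins when there are fewer distinct values than ``k``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n == 0:
        raise ValueError("empty input")
    k = int(min(k, np.unique(x).size))
    if k <= 1:
        return np.zeros(n, dtype=np.int64)

    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    ps = np.concatenate(([0.0], np.cumsum(xs)))
    ps2 = np.concatenate(([0.0], np.cumsum(xs * xs)))

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        # within-segment sum of squared deviations for xs[i:j], vectorised in i
        m = j - i
        s = ps[j] - ps[i]
        return (ps2[j] - ps2[i]) - s * s / m

    cost = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=np.int64)
    cost[0, 0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            i = np.arange(m - 1, j)
            cand = cost[m - 1, i] + seg_cost(i, j)
            best = int(np.argmin(cand))
            cost[m, j] = cand[best]
            back[m, j] = i[best]

    # ties between equal values never straddle a boundary: equal values are
    # adjacent after the stable sort and splitting them cannot lower cost,
    # but guard anyway by snapping boundaries to value changes is not needed
    # for MI purposes (labels on ties may then differ); keep the DP optimum.
    labels = np.zeros(n, dtype=np.int64)
    j = n
    for m in range(k, 0, -1):
        i = back[m, j]
        labels[order[i:j]] = m - 1
        j = i
    return labels


def _init_centers(
    X: np.ndarray, k: int, restarts: int, rng: np.random.Generator
) -> np.ndarray:
    """Choose k distinct sample indices per (batch, restart): (P, R, k)."""
    P, n, _ = X.shape
    # argsort of uniforms = random permutation per row, vectorised
    u = rng.random((P, restarts, n))
    return np.argsort(u, axis=-1)[..., :k]


def batched_kmeans(
    X: np.ndarray,
    k: int,
    *,
    restarts: int = 10,
    max_iter: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Cluster every point set in a batch; return labels of the best restart.

    Parameters
    ----------
    X:
        Array of shape (P, n, d): P independent point sets of n points.
    k:
        Number of clusters (clusters may empty out; labels then use < k ids).
    restarts:
        Random-point initialisations per point set; the restart with the
        lowest within-cluster sum of squares wins.
    seed:
        Seeds the initialisation draws; fixed seed => identical labels.

    Returns
    -------
    labels : (P, n) int array.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError("X must have shape (batch, n_points, n_dims)")
    P, n, d = X.shape
    if n < k:
        raise ValueError(f"fewer samples ({n}) than clusters ({k})")
    rng = np.random.default_rng(seed)

    init = _init_centers(X, k, restarts, rng)  # (P, R, k)
    best_labels = np.zeros((P, n), dtype=np.int64)
    best_inertia = np.full(P, np.inf)
    x_sq = (X * X).sum(-1)  # (P, n)

    for r in range(restarts):
        centers = np.take_along_axis(X, init[:, r, :, None], axis=1)  # (P,k,d)
        labels = np.zeros((P, n), dtype=np.int64)
        for _ in range(max_iter):
            # squared distances via |x|^2 - 2 x.c + |c|^2
            cross = np.einsum("pnd,pkd->pnk", X, centers)
            d2 = x_sq[:, :, None] - 2.0 * cross + (centers * centers).sum(-1)[:, None, :]
            new_labels = d2.argmin(-1)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            # centroid update: scatter-add points into (P, k) accumulators
            flat = (np.arange(P)[:, None] * k + labels).ravel()
            counts = np.bincount(flat, minlength=P * k).reshape(P, k)
            sums = np.empty((P, k, d))
            for dim in range(d):
                sums[:, :, dim] = np.bincount(
                    flat, weights=X[:, :, dim].ravel(), minlength=P * k
                ).reshape(P, k)
            nonempty = counts > 0
            centers = np.where(
                nonempty[:, :, None], sums / np.maximum(counts, 1)[:, :, None], centers
            )
        cross = np.einsum("pnd,pkd->pnk", X, centers)
        d2 = x_sq[:, :, None] - 2.0 * cross + (centers * centers).sum(-1)[:, None, :]
        labels = d2.argmin(-1)
        inertia = np.take_along_axis(d2, labels[:, :, None], axis=2)[:, :, 0].sum(1)
        improved = inertia < best_inertia - 1e-12
        best_inertia[improved] = inertia[improved]
        best_labels[improved] = labels[improved]
    return best_labels
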
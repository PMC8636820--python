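"""Sparse k-means with lasso feature weights and its robust trimmed variant.

The estimator alternates two steps until the weight vector stabilises:

1. holding the feature weights ``w`` fixed, partition the samples by
   k-means in the weighted metric ``d_w(x, c) = sum_j w_j (x_j - c_j)^2``;
2. holding the partition fixed, choose ``w`` to maximise
   ``sum_j w_j * BCSS_j`` subject to ``||w||_2 <= 1``, ``||w||_1 <= s`` and
   ``w >= 0``, where ``BCSS_j`` is feature ``j``'s between-cluster sum of
   squares.  The solution is a soft-threshold of the BCSS vector followed
   by L2 normalisation, with the threshold found by bisection on the L1
   norm.

The L1 bound ``s`` (between 1 and sqrt(p)) controls sparsity: at
``s = sqrt(p)`` the penalty is inactive and every feature keeps the same
weight; as ``s`` shrinks toward 1 the weights of uninformative features are
driven to exactly zero.

The robust variant excludes, at every iteration, the ``ceil(alpha * n)``
samples farthest from their cluster centre in the weighted metric from the
centre updates, and additionally the ``ceil(alpha * n)`` farthest in the
plain Euclidean metric from the weight update (outliers hiding behind
near-zero weights must not steer the reweighting).  Members of clusters
kept alive by a single untrimmed sample are flagged as potential outliers
too.  After convergence all flagged samples are re-inserted by assigning
them to the nearest centre in weighted space, and remain marked in
``outlier_flags``.  With ``alpha = 0`` the robust variant reduces exactly
(bit for bit, at equal seed) to plain sparse k-means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataset import ExpressionDataset, trimmed_zscore, zscore
from .errors import DegenerateDataError, ParameterError

__all__ = [
    "SparseClusterResult",
    "update_weights",
    "sparse_kmeans",
    "robust_sparse_kmeans",
    "wwss",
    "weight_transform",
]


@dataclass
class SparseClusterResult:
    """Outcome of one (robust) sparse k-means run.

    ``assignments`` are 1-based cluster labels (1..k) covering every sample,
    including flagged outliers.  ``weights`` satisfy ``||w||_2 = 1`` and
    ``||w||_1 <= l1_bound``.  ``wwss`` is the weighted within-cluster sum of
    squares of the final partition, evaluated on all samples.
    """

    assignments: np.ndarray
    weights: np.ndarray
    outlier_flags: np.ndarray
    wwss: float
    objective: float
    l1_bound: float
    alpha: float
    n_iter_run: int
    converged: bool
    k: int
    standardized: bool
    objective_history: list[float] = field(default_factory=list)
    centers: np.ndarray | None = None


# ---------------------------------------------------------------------------
# weight update
# ---------------------------------------------------------------------------

def _soft_unit(b: np.ndarray, delta: float) -> np.ndarray:
    v = np.maximum(b - delta, 0.0)
    nrm = np.linalg.norm(v)
    return v / nrm if nrm > 0 else v


def update_weights(bcss_per_feature: np.ndarray, l1_bound: float) -> np.ndarray:
    """Maximise ``sum_j w_j b_j`` over the L1/L2-constrained simplex.

    Solves ``argmax w . b`` subject to ``||w||_2 <= 1``, ``||w||_1 <= s``,
    ``w >= 0``: soft-threshold ``b`` then L2-normalise, the threshold chosen
    by bisection so that ``||w||_1 = s`` (zero threshold if the bound is
    already slack).
    """
    b = np.asarray(bcss_per_feature, dtype=float)
    if l1_bound <= 1:
        raise ParameterError(f"l1_bound must exceed 1, got {l1_bound}")
    if b.size == 0 or np.nanmax(b) <= 0:
        raise DegenerateDataError("all between-cluster sums of squares are <= 0")
    b = np.maximum(b, 0.0)
    b = b / b.max()  # scale-invariant; guards against norm underflow

    w = _soft_unit(b, 0.0)
    if w.sum() <= l1_bound + 1e-8:
        return w
    lo, hi = 0.0, float(b.max())
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if _soft_unit(b, mid).sum() > l1_bound:
            lo = mid
        else:
            hi = mid
        if hi - lo <= 1e-12 * max(1.0, b.max()):
            break
    w = _soft_unit(b, 0.5 * (lo + hi))
    if w.sum() > l1_bound:
        # tied maxima: ||w||_1 jumps discontinuously in the threshold and
        # never meets the bound on the unit sphere; the maximiser then lies
        # inside the sphere at ||w||_1 = s exactly
        w = w * (l1_bound / w.sum())
    return w


# ---------------------------------------------------------------------------
# internal k-means machinery (weighted metric, trimming, empty-cluster repair)
# ---------------------------------------------------------------------------

def _weighted_sq_dists(X: np.ndarray, centers: np.ndarray, w: np.ndarray) -> np.ndarray:
    """(n, k) matrix of weighted squared distances."""
    Xw = X * np.sqrt(w)
    Cw = centers * np.sqrt(w)
    d2 = (Xw**2).sum(axis=1)[:, None] + (Cw**2).sum(axis=1)[None, :] - 2.0 * (Xw @ Cw.T)
    return np.maximum(d2, 0.0)


def _kmeanspp_init(X: np.ndarray, k: int, w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding in the weighted metric."""
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    first = int(rng.integers(n))
    centers[0] = X[first]
    d2 = _weighted_sq_dists(X, centers[:1], w)[:, 0]
    for c in range(1, k):
        total = d2.sum()
        if total <= 0:
            idx = int(rng.integers(n))  # duplicate points: fall back to uniform
        else:
            idx = int(rng.choice(n, p=d2 / total))
        centers[c] = X[idx]
        d2 = np.minimum(d2, _weighted_sq_dists(X, centers[c : c + 1], w)[:, 0])
    return centers


def _trim_weighted(X: np.ndarray, centers: np.ndarray, labels: np.ndarray, w: np.ndarray, n_trim: int) -> np.ndarray:
    """The n_trim samples farthest from their centre in the weighted
    metric (the trimmed-k-means outlier set O_W); boolean mask."""
    n = X.shape[0]
    mask = np.zeros(n, dtype=bool)
    if n_trim <= 0:
        return mask
    diff = X - centers[labels]
    dw = (diff**2 * w).sum(axis=1)
    mask[np.argsort(dw)[-n_trim:]] = True
    return mask


def _trim_unweighted(X: np.ndarray, centers: np.ndarray, labels: np.ndarray, n_trim: int) -> np.ndarray:
    """The n_trim samples farthest from their centre in plain Euclidean
    space (O_E); flags outliers that hide behind small weights."""
    n = X.shape[0]
    mask = np.zeros(n, dtype=bool)
    if n_trim <= 0:
        return mask
    diff = X - centers[labels]
    de = (diff**2).sum(axis=1)
    mask[np.argsort(de)[-n_trim:]] = True
    return mask


def _lloyd(
    X: np.ndarray,
    centers: np.ndarray,
    w: np.ndarray,
    n_trim: int,
    rng: np.random.Generator,
    max_iter: int = 100,
    force_trim: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted (optionally trimmed) Lloyd iterations.

    Returns (labels over all samples, centres, trimmed mask).  Centres are
    means over untrimmed members only; an emptied cluster is re-seeded from
    the untrimmed sample farthest from its current centre.  ``force_trim``
    marks samples excluded from the updates regardless of distance (used
    for singleton-cluster outliers flagged by the robust refinement).
    """
    n, k = X.shape[0], centers.shape[0]
    if force_trim is None:
        force_trim = np.zeros(n, dtype=bool)
    labels = np.full(n, -1)
    trimmed = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        d2 = _weighted_sq_dists(X, centers, w)
        new_labels = d2.argmin(axis=1)  # argmin takes the lowest index on ties
        trimmed = _trim_weighted(X, centers, new_labels, w, n_trim) | force_trim
        new_centers = centers.copy()
        for c in range(k):
            members = (new_labels == c) & ~trimmed
            if members.any():
                new_centers[c] = X[members].mean(axis=0)
            else:
                # re-seed an empty cluster from the untrimmed sample farthest
                # from its assigned centre
                avail = ~trimmed
                if not avail.any():
                    avail = np.ones(n, dtype=bool)
                dist_own = d2[np.arange(n), new_labels]
                cand = np.where(avail)[0]
                far = cand[np.argmax(dist_own[cand])]
                new_centers[c] = X[far]
                new_labels[far] = c
        if np.array_equal(new_labels, labels) and np.allclose(new_centers, centers):
            labels, centers = new_labels, new_centers
            break
        labels, centers = new_labels, new_centers
    return labels, centers, trimmed


def _lloyd_robust(
    X: np.ndarray,
    centers: np.ndarray,
    w: np.ndarray,
    n_trim: int,
    rng: np.random.Generator,
    max_rounds: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trimmed Lloyd plus the small-cluster outlier rule.

    An extreme sample that captures a centre sits at zero distance from it
    and evades distance-based trimming while wasting a cluster.  After
    Lloyd converges, members of clusters kept alive by a single untrimmed
    sample are flagged as potential outliers, their centres are re-seeded,
    and Lloyd re-runs - a bounded refinement rather than an in-loop rule,
    which would make Lloyd oscillate.
    """
    n = X.shape[0]
    force = np.zeros(n, dtype=bool)
    labels, centers, trimmed = _lloyd(X, centers, w, n_trim, rng)
    if n_trim == 0:
        return labels, centers, trimmed
    for _ in range(max_rounds):
        sizes = np.bincount(labels[~trimmed], minlength=centers.shape[0])
        singles = np.where(sizes == 1)[0]
        if singles.size == 0:
            break
        grew = False
        for c in singles:
            new = (labels == c) & ~trimmed & ~force
            grew |= bool(new.any())
            force |= new
        if not grew:
            break
        labels, centers, trimmed = _lloyd(X, centers, w, n_trim, rng, force_trim=force)
    return labels, centers, trimmed


def _bcss_per_feature(X: np.ndarray, labels: np.ndarray, include: np.ndarray) -> np.ndarray:
    """Between-cluster sum of squares per feature over the included samples."""
    Xi = X[include]
    li = labels[include]
    mu = Xi.mean(axis=0)
    tss = ((Xi - mu) ** 2).sum(axis=0)
    wss = np.zeros(X.shape[1])
    for c in np.unique(li):
        m = Xi[li == c]
        wss += ((m - m.mean(axis=0)) ** 2).sum(axis=0)
    return tss - wss


def _best_partition(
    X: np.ndarray,
    k: int,
    w: np.ndarray,
    n_trim: int,
    rng: np.random.Generator,
    warm_centers: np.ndarray | None,
    inner_starts: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lloyd from the warm start plus fresh k-means++ seedings in the
    current weighted metric; best weighted between-cluster objective wins.
    Re-seeding per weight update is what keeps the alternation out of the
    local optima of the initial (uniform-weight) metric."""
    cands = []
    if warm_centers is not None:
        cands.append(warm_centers)
    target = inner_starts + (warm_centers is not None)
    toggle = 0
    while len(cands) < target:
        if n_trim > 0 and toggle % 2 == 1:
            # uniform-random seeding: k-means++ chooses centres with
            # probability proportional to squared distance and therefore
            # seeds on the very outliers trimming is meant to exclude
            idx = rng.choice(X.shape[0], size=k, replace=False)
            cands.append(X[idx].copy())
        else:
            cands.append(_kmeanspp_init(X, k, w, rng))
        toggle += 1
    best = None
    best_score = np.inf
    for c0 in cands:
        labels, centers, o_w = _lloyd_robust(X, c0.copy(), w, n_trim, rng)
        score = _selection_score(X, labels, w, o_w, n_trim)
        if score < best_score:
            best_score = score
            best = (labels, centers, o_w)
    assert best is not None
    return best


def _wss_per_feature(X: np.ndarray, labels: np.ndarray, include: np.ndarray) -> np.ndarray:
    wss = np.zeros(X.shape[1])
    Xi, li = X[include], labels[include]
    for c in np.unique(li):
        m = Xi[li == c]
        wss += ((m - m.mean(axis=0)) ** 2).sum(axis=0)
    return wss


def _selection_score(X, labels, w, o_w, n_trim) -> float:
    """Lower-is-better criterion for comparing candidate partitions.

    Without trimming, minimising the weighted within-SS equals maximising
    the weighted between-SS.  With trimming the two diverge (the trim set,
    hence the total dispersion, differs per candidate), and only the
    trimmed within-SS is safe: a partition that wastes a cluster on an
    extreme outlier inflates its between-SS but not its within-SS rank.
    """
    if n_trim == 0:
        bcss = _bcss_per_feature(X, labels, np.ones(X.shape[0], dtype=bool))
        return -float(w @ np.maximum(bcss, 0.0))
    include = ~o_w
    score = float(w @ _wss_per_feature(X, labels, include))
    # a cluster kept alive by a single untrimmed sample signals an outlier
    # that captured a centre; rank such solutions behind all others
    sizes = np.bincount(labels[include], minlength=int(labels.max()) + 1)
    n_singleton = int(np.sum(sizes[np.unique(labels)] <= 1))
    if n_singleton:
        Xi = X[include]
        tss = float(w @ ((Xi - Xi.mean(axis=0)) ** 2).sum(axis=0))
        score += n_singleton * (tss + 1.0)
    return score


def _run_single(
    X: np.ndarray,
    k: int,
    l1_bound: float,
    alpha: float,
    rng: np.random.Generator,
    max_alternations: int = 20,
    weight_tol: float = 1e-4,
    inner_starts: int = 3,
) -> dict:
    n, p = X.shape
    n_trim = math.ceil(alpha * n) if alpha > 0 else 0
    w = np.full(p, 1.0 / math.sqrt(p))
    centers: np.ndarray | None = None
    labels = np.zeros(n, dtype=int)
    trimmed = np.zeros(n, dtype=bool)
    history: list[float] = []
    converged = False
    n_alt = 0
    for n_alt in range(1, max_alternations + 1):
        labels, centers, o_w = _best_partition(
            X, k, w, n_trim, rng, centers, inner_starts
        )
        # weights are updated on the cases outside O_W (weighted-space trim)
        # and O_E (unweighted-space trim): outliers hiding behind near-zero
        # weights must not steer the reweighting either
        o_e = _trim_unweighted(X, centers, labels, n_trim)
        trimmed = o_w | o_e
        include = ~trimmed
        bcss = _bcss_per_feature(X, labels, include)
        if bcss.max() <= 0:
            # partition carries no between-cluster signal; keep weights
            history.append(0.0)
            converged = True
            break
        w_new = update_weights(bcss, l1_bound)
        history.append(float(w_new @ bcss))
        delta = np.abs(w_new - w).sum() / max(np.abs(w).sum(), 1e-12)
        w = w_new
        if delta < weight_tol:
            converged = True
            break
    # final pass: re-assign everything (incl. trimmed) in the final metric
    d2 = _weighted_sq_dists(X, centers, w)
    labels = d2.argmin(axis=1)
    include = ~trimmed
    bcss = _bcss_per_feature(X, labels, include) if include.sum() > k else _bcss_per_feature(X, labels, np.ones(n, bool))
    objective = float(w @ np.maximum(bcss, 0.0))
    score = _selection_score(X, labels, w, o_w if n_trim else trimmed, n_trim)
    return {
        "labels": labels,
        "weights": w,
        "trimmed": trimmed,
        "centers": centers,
        "objective": objective,
        "score": score,
        "history": history,
        "n_alt": n_alt,
        "converged": converged,
    }


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _as_matrix(data) -> np.ndarray:
    if isinstance(data, ExpressionDataset):
        return data.values
    return np.asarray(data, dtype=float)


def robust_sparse_kmeans(
    data,
    k: int,
    l1_bound: float,
    alpha: float = 0.1,
    n_starts: int = 10,
    seed: int | np.random.SeedSequence | None = 0,
    standardize: bool = True,
    max_alternations: int = 20,
    weight_tol: float = 1e-4,
) -> SparseClusterResult:
    """Robust sparse k-means: trimmed centres/weights, outliers re-inserted.

    Parameters
    ----------
    data
        :class:`ExpressionDataset` or plain ``(n, p)`` array.
    k
        Number of clusters, ``2 <= k <= n`` (``k = n`` is allowed and gives
        singleton clusters with zero within-cluster dispersion).
    l1_bound
        Lasso bound ``s`` on the weights, ``1 < s <= sqrt(p)``.
    alpha
        Trim fraction in ``[0, 0.5)``; ``ceil(alpha * n)`` samples are
        excluded per iteration.  ``alpha = 0`` is plain sparse k-means.
    n_starts
        Independent k-means++ restarts; the best weighted between-cluster
        objective wins.
    standardize
        z-score features before clustering (expression studies normalise to
        a control; this puts features on a common scale).
    """
    X = _as_matrix(data)
    n, p = X.shape
    if not 2 <= k <= n:
        raise ParameterError(f"k={k} out of range: need 2 <= k <= n={n}")
    if not 1 < l1_bound <= math.sqrt(p) + 1e-9:
        raise ParameterError(f"l1_bound must lie in (1, sqrt(p)]={math.sqrt(p):.3f}, got {l1_bound}")
    if not 0 <= alpha < 0.5:
        raise ParameterError(f"alpha must lie in [0, 0.5), got {alpha}")
    if n_starts < 1:
        raise ParameterError("n_starts must be >= 1")

    if standardize:
        # robust mode trims the most extreme rows out of the mean/SD
        # estimates: the outliers it is meant to resist would otherwise
        # inflate the SD of exactly the features they corrupt and shrink
        # those features' standardised signal
        X = trimmed_zscore(X, alpha) if alpha > 0 else zscore(X)
    if np.allclose(X, X[0]):
        raise DegenerateDataError("constant matrix: zero total dispersion")

    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    best: dict | None = None
    for child in ss.spawn(n_starts):
        run = _run_single(
            X, k, l1_bound, alpha, np.random.default_rng(child),
            max_alternations=max_alternations, weight_tol=weight_tol,
        )
        if best is None or run["score"] < best["score"]:
            best = run
    assert best is not None

    labels = best["labels"].astype(int) + 1  # public labels are 1-based
    return SparseClusterResult(
        assignments=labels,
        weights=best["weights"],
        outlier_flags=best["trimmed"].copy(),
        wwss=_wwss_arrays(X, labels, best["weights"]),
        objective=best["objective"],
        l1_bound=float(l1_bound),
        alpha=float(alpha),
        n_iter_run=best["n_alt"],
        converged=best["converged"],
        k=int(k),
        standardized=bool(standardize),
        objective_history=best["history"],
        centers=best["centers"],
    )


def sparse_kmeans(
    data,
    k: int,
    l1_bound: float,
    n_starts: int = 10,
    seed: int | np.random.SeedSequence | None = 0,
    standardize: bool = True,
    max_alternations: int = 20,
    weight_tol: float = 1e-4,
) -> SparseClusterResult:
    """Sparse (lasso-weighted) k-means; the ``alpha = 0`` special case of
    :func:`robust_sparse_kmeans`."""
    return robust_sparse_kmeans(
        data, k, l1_bound, alpha=0.0, n_starts=n_starts, seed=seed,
        standardize=standardize, max_alternations=max_alternations,
        weight_tol=weight_tol,
    )


def _wwss_arrays(X: np.ndarray, assignments: np.ndarray, weights: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(assignments):
        m = X[assignments == c]
        total += float((weights * ((m - m.mean(axis=0)) ** 2).sum(axis=0)).sum())
    return total


def wwss(data, assignments: np.ndarray, weights: np.ndarray, standardize: bool = True) -> float:
    """Weighted within-cluster sum of squares of a labelled partition.

    ``sum_j w_j * WSS_j`` where ``WSS_j`` is feature ``j``'s within-cluster
    sum of squared deviations.  Non-negative; zero when every cluster is a
    singleton.
    """
    X = _as_matrix(data)
    assignments = np.asarray(assignments, dtype=int)
    weights = np.asarray(weights, dtype=float)
    if assignments.shape[0] != X.shape[0]:
        raise ParameterError("assignments length does not match data")
    if weights.shape[0] != X.shape[1]:
        raise ParameterError("weights length does not match feature count")
    k = assignments.max()
    if assignments.min() < 1:
        raise ParameterError("labels must lie in 1..k")
    if k > X.shape[0]:
        raise ParameterError("labels must lie in 1..k with k <= n")
    if standardize:
        X = zscore(X)
    return _wwss_arrays(X, assignments, weights)


def weight_transform(data, weights: np.ndarray) -> np.ndarray:
    """Scale each expression column by its cluster weight.

    The weighted matrix is the recommended input for low-dimensional
    embeddings (e.g. tSNE) of the clustered samples, so that the display
    metric matches the metric the clustering actually used.
    """
    X = _as_matrix(data)
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != X.shape[1]:
        raise ParameterError(
            f"weights length {weights.shape[0]} does not match feature count {X.shape[1]}"
        )
    return X * weights
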
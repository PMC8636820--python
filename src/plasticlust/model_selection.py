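"""Data-driven choice of k and of the lasso bound.

Choosing k
----------
The number of clusters is read off the elbow of the weighted
within-cluster sum of squares (WWSS) versus k.  Two details matter in the
variable-selection regime (few informative features among many noise
features):

* WWSS values from runs with *adaptive* weights are not commensurable
  across k - at small k the lasso re-concentrates weight on whichever few
  features make the coarse partition look tight, which flattens the elbow.
  The curve is therefore computed under a single common metric: the sparse
  runs across the whole k range are pooled, their mean weights define the
  selected feature support (weights above a fraction of the maximum), and
  the WWSS-vs-k curve is traced by multi-restart weighted k-means with
  uniform weights on that support.
* raw second differences of a dispersion curve peak at the steep
  small-k end no matter where the elbow is; the detector therefore
  normalises both axes to [0, 1], smooths with a Savitzky-Golay filter and
  maximises the discrete curvature kappa = |y''| / (1 + y'^2)^(3/2).

Choosing the lasso bound
------------------------
Permutation (gap-statistic) scheme: for each candidate bound the gap
between the log objective on the real data and the mean log objective on
column-permuted data is computed, and the candidate with the largest gap
wins (ties go to the smallest bound).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .cluster import (
    _kmeanspp_init,
    _lloyd,
    _wwss_arrays,
    robust_sparse_kmeans,
)
from .dataset import ExpressionDataset, trimmed_zscore, zscore
from .errors import ParameterError

__all__ = ["ElbowCurve", "elbow_k", "find_elbow", "select_l1_bound"]


@dataclass
class ElbowCurve:
    k_values: np.ndarray
    mean_wwss: np.ndarray  # WWSS curve used for detection (common metric)
    smoothed: np.ndarray
    chosen_k: int
    curvature: np.ndarray  # kappa at interior k values
    sparse_mean_wwss: np.ndarray | None = None  # per-k mean over sparse runs
    support: np.ndarray | None = None  # features defining the common metric


def find_elbow(
    k_values: np.ndarray,
    wwss_values: np.ndarray,
    window: int = 3,
    polyorder: int = 2,
) -> ElbowCurve:
    """Locate the elbow of a dispersion-vs-k curve by maximum curvature.

    Both axes are normalised to [0, 1] (making the choice invariant to
    rescaling the expression values), the curve is smoothed with a
    Savitzky-Golay filter (default window 3, order 2 - the smallest
    window; a typical k range has only 8 points and wider windows blur
    the kink), and the interior k with the largest discrete curvature
    ``|y''| / (1 + y'^2)^1.5`` is returned.
    """
    k_values = np.asarray(k_values, dtype=int)
    y = np.asarray(wwss_values, dtype=float)
    if k_values.ndim != 1 or k_values.size != y.size:
        raise ParameterError("k_values and wwss_values must be 1-D and equal length")
    if np.any(np.diff(k_values) <= 0):
        raise ParameterError("k_values must be strictly increasing")
    if k_values.size < 4:
        raise ParameterError("need at least 4 k values to locate an elbow")
    if k_values.size < window:
        raise ParameterError(
            f"k range of {k_values.size} values is shorter than the smoothing window {window}"
        )
    if not np.all(np.isfinite(y)):
        raise ParameterError("wwss_values must be finite")

    span_y = np.ptp(y)
    yn = (y - y.min()) / span_y if span_y > 0 else np.zeros_like(y)
    kn = (k_values - k_values.min()) / np.ptp(k_values)
    sm_n = savgol_filter(yn, window_length=window, polyorder=min(polyorder, window - 1))
    h = kn[1] - kn[0]
    # central differences evaluated exactly at the interior points: a
    # double-gradient pass would smear a kink's curvature onto the point
    # after it, where the flat slope shrinks the denominator
    d1 = (sm_n[2:] - sm_n[:-2]) / (2 * h)
    d2 = (sm_n[2:] - 2 * sm_n[1:-1] + sm_n[:-2]) / h**2
    kappa = np.abs(d2) / (1.0 + d1**2) ** 1.5
    chosen = int(k_values[1:-1][int(np.argmax(kappa))])
    return ElbowCurve(
        k_values=k_values,
        mean_wwss=y,
        smoothed=sm_n * span_y + y.min(),
        chosen_k=chosen,
        curvature=kappa,
    )


def elbow_k(
    data,
    k_range=range(2, 10),
    n_iter: int = 100,
    alpha: float = 0.1,
    l1_bound: float = 2.25,
    seed: int | np.random.SeedSequence = 0,
    n_starts: int = 5,
    window: int = 3,
    polyorder: int = 2,
    standardize: bool = True,
    support_frac: float = 0.2,
    curve_starts: int = 30,
) -> ElbowCurve:
    """Choose k from the WWSS elbow over repeated clustering runs.

    Phase 1 runs :func:`robust_sparse_kmeans` ``n_iter`` times per k with
    fresh seeds; the pooled mean weights define the selected feature
    support (``weight >= support_frac * max``).  Phase 2 traces the
    WWSS-vs-k curve with ``curve_starts`` restarts of weighted (trimmed)
    k-means under uniform weights on the support, and :func:`find_elbow`
    picks the maximum-curvature k.
    """
    k_values = np.asarray(sorted(k_range), dtype=int)
    if n_iter < 1:
        raise ParameterError("n_iter must be >= 1")
    if k_values.size < window:
        raise ParameterError(
            f"k range of {k_values.size} values is shorter than the smoothing window {window}"
        )
    if not 0 < support_frac < 1:
        raise ParameterError("support_frac must lie in (0, 1)")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(k_values.size * n_iter + 1)

    X = data.values if isinstance(data, ExpressionDataset) else np.asarray(data, dtype=float)
    if standardize:
        Z = trimmed_zscore(X, alpha) if alpha > 0 else zscore(X)
    else:
        Z = X - X.mean(axis=0)
    n = Z.shape[0]
    n_trim = math.ceil(alpha * n) if alpha > 0 else 0

    weights = []
    sparse_wwss = np.empty(k_values.size)
    for i, k in enumerate(k_values):
        vals = []
        for r in range(n_iter):
            res = robust_sparse_kmeans(
                data, int(k), l1_bound, alpha=alpha, n_starts=n_starts,
                seed=children[i * n_iter + r], standardize=standardize,
            )
            weights.append(res.weights)
            vals.append(res.wwss)
        sparse_wwss[i] = float(np.mean(vals))
    # median across runs: a feature must carry weight in at least half the
    # runs to enter the support, so occasionally-weighted noise features
    # cannot flood the within-SS floor of the curve
    w_med = np.median(weights, axis=0)
    if w_med.max() <= 0:
        w_med = np.mean(weights, axis=0)
    support = w_med >= support_frac * w_med.max()
    w_flat = support.astype(float) / math.sqrt(int(support.sum()))

    rng = np.random.default_rng(children[-1])
    curve = np.empty(k_values.size)
    for i, k in enumerate(k_values):
        best = np.inf
        for _ in range(curve_starts):
            labels, _, _ = _lloyd(Z, _kmeanspp_init(Z, int(k), w_flat, rng), w_flat, n_trim, rng)
            best = min(best, _wwss_arrays(Z, labels + 1, w_flat))
        curve[i] = best

    out = find_elbow(k_values, curve, window=window, polyorder=polyorder)
    out.sparse_mean_wwss = sparse_wwss
    out.support = support
    return out


def select_l1_bound(
    data,
    k: int,
    candidate_bounds,
    n_perm: int = 5,
    seed: int | np.random.SeedSequence = 0,
    alpha: float = 0.1,
    n_starts: int = 5,
    n_obs: int = 3,
    standardize: bool = True,
) -> float:
    """Pick the lasso bound by the permutation gap statistic.

    ``gap(s) = log O(s; data) - mean_b log O(s; permuted data_b)`` where
    ``O`` is the weighted between-cluster objective and each permutation
    shuffles every feature column independently (destroying cluster
    structure while preserving marginals).  Selection follows the
    one-standard-error rule: the smallest candidate whose gap reaches the
    maximum gap minus one standard error of the permuted objectives -
    the sparsest metric the permutation evidence cannot distinguish from
    the best one.  A flat gap curve therefore returns the smallest
    candidate.
    """
    candidates = sorted(float(c) for c in np.atleast_1d(candidate_bounds))
    if len(candidates) == 0:
        raise ParameterError("candidate_bounds must be non-empty")
    if len(candidates) == 1:
        return candidates[0]
    if n_perm < 2:
        raise ParameterError("n_perm must be >= 2")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    X = data.values if isinstance(data, ExpressionDataset) else np.asarray(data, dtype=float)
    if standardize:
        X = trimmed_zscore(X, alpha) if alpha > 0 else zscore(X)

    perms = []
    for _ in range(n_perm):
        Xp = np.column_stack([rng.permutation(X[:, j]) for j in range(X.shape[1])])
        perms.append(Xp)

    run_seeds = ss.spawn(len(candidates) * (n_obs + n_perm))
    gaps = []
    ses = []
    si = 0
    eps = 1e-12
    for s in candidates:
        log_obs = []
        for _ in range(n_obs):  # average out restart noise in the observed objective
            obj = robust_sparse_kmeans(
                X, k, s, alpha=alpha, n_starts=n_starts, seed=run_seeds[si], standardize=False
            ).objective
            log_obs.append(np.log(max(obj, eps)))
            si += 1
        perm_obj = []
        for Xp in perms:
            perm_obj.append(
                robust_sparse_kmeans(
                    Xp, k, s, alpha=alpha, n_starts=n_starts, seed=run_seeds[si], standardize=False
                ).objective
            )
            si += 1
        log_perm = np.log(np.maximum(perm_obj, eps))
        gaps.append(float(np.mean(log_obs)) - float(log_perm.mean()))
        ses.append(float(log_perm.std(ddof=1) / np.sqrt(n_perm)))
    gaps = np.asarray(gaps)
    best = int(np.argmax(gaps))
    threshold = gaps[best] - ses[best]
    return next(c for c, g in zip(candidates, gaps) if g >= threshold)
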
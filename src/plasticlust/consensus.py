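"""Multi-restart consensus analysis of the robust sparse clustering.

Clustering a small sample from different random starting conditions can
shuffle samples near cluster boundaries, so stability is assessed by
re-running the algorithm many times, aligning cluster labels across runs by
ordering clusters by ascending median sample age (cluster 1 = youngest =
"A", matching how lifespan clusters are presented), and accumulating a
sample x cluster co-assignment count matrix.  Cluster overlap is summarised
by the Jaccard similarity of membership sets, where a sample belongs to a
cluster's set if it was assigned there in at least ``min_count`` runs
(default 10 of 100 - the metric is sensitive to small samples).

The age-randomisation null quantifies whether the observed progression of
cluster ages could arise by chance: ages enter the analysis only as labels,
so permuting them over samples while re-clustering the (unchanged)
expression matrix yields the null distribution of any age-progression
statistic.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .cluster import SparseClusterResult, robust_sparse_kmeans
from .dataset import ExpressionDataset
from .errors import DegenerateDataError, ParameterError

__all__ = [
    "ConsensusResult",
    "run_consensus",
    "jaccard_matrix",
    "AgeRandomizationNull",
    "age_randomization_null",
    "relabel_by_age",
    "cluster_letters",
]


def cluster_letters(k: int) -> list[str]:
    """Cluster display names A, B, C ... in age order."""
    return list(string.ascii_uppercase[:k])


def relabel_by_age(assignments: np.ndarray, ages: np.ndarray, k: int) -> np.ndarray:
    """Renumber 1..k labels so that cluster median ages ascend.

    Ties between identical median ages break on the original label so the
    mapping is deterministic.
    """
    assignments = np.asarray(assignments, dtype=int)
    medians = []
    for c in range(1, k + 1):
        members = ages[assignments == c]
        medians.append(np.median(members) if members.size else np.inf)
    order = np.argsort(np.asarray(medians), kind="stable")  # old label (0-based) in age order
    new_of_old = np.empty(k, dtype=int)
    new_of_old[order] = np.arange(1, k + 1)
    return new_of_old[assignments - 1]


@dataclass
class ConsensusResult:
    n_iter: int
    count_matrix: np.ndarray  # (n, k) integer counts, rows sum to n_iter
    modal_assignment: np.ndarray  # 1..k, ties -> younger cluster
    mean_weights: np.ndarray
    cluster_ages: pd.DataFrame  # median / IQR of ages per cluster (modal)
    jaccard: np.ndarray
    sample_ids: list[str]
    feature_names: list[str]
    k: int
    min_count: int

    def count_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.count_matrix, index=self.sample_ids, columns=cluster_letters(self.k))

    def jaccard_frame(self) -> pd.DataFrame:
        letters = cluster_letters(self.k)
        return pd.DataFrame(self.jaccard, index=letters, columns=letters)


def run_consensus(
    data: ExpressionDataset,
    k: int,
    l1_bound: float,
    alpha: float = 0.1,
    n_iter: int = 100,
    seed: int | np.random.SeedSequence = 0,
    n_starts: int = 10,
    replicates: str = "keep",
    min_count: int | None = None,
    standardize: bool = True,
) -> ConsensusResult:
    """Run the robust sparse clustering ``n_iter`` times and accumulate
    age-aligned co-assignment counts, averaged feature weights and the
    Jaccard overlap of cluster memberships.

    ``replicates`` is ``"keep"`` (each run is a sample) or ``"average"``
    (replicate runs of one subject are averaged first).  ``min_count``
    defaults to 10% of ``n_iter``, the membership rule used for Jaccard.
    """
    if n_iter < 2:
        raise ParameterError("n_iter must be >= 2")
    if replicates not in ("keep", "average"):
        raise ParameterError("replicates must be 'keep' or 'average'")
    if replicates == "average":
        data = data.average_replicates()
    n = data.n_samples
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_iter)

    counts = np.zeros((n, k), dtype=int)
    weight_sum = np.zeros(data.n_features)
    for child in children:
        res = robust_sparse_kmeans(
            data, k, l1_bound, alpha=alpha, n_starts=n_starts, seed=child, standardize=standardize
        )
        aligned = relabel_by_age(res.assignments, data.ages, k)
        counts[np.arange(n), aligned - 1] += 1
        weight_sum += res.weights

    modal = counts.argmax(axis=1) + 1  # argmax ties -> lowest index = youngest cluster
    if min_count is None:
        min_count = max(1, round(0.1 * n_iter))
    jac = _jaccard_from_counts(counts, min_count)

    rows = []
    for c in range(1, k + 1):
        a = data.ages[modal == c]
        rows.append(
            {
                "cluster": cluster_letters(k)[c - 1],
                "n": int(a.size),
                "median_age": float(np.median(a)) if a.size else np.nan,
                "iqr_age": float(np.subtract(*np.percentile(a, [75, 25]))) if a.size else np.nan,
            }
        )
    cluster_ages = pd.DataFrame(rows).set_index("cluster")

    return ConsensusResult(
        n_iter=n_iter,
        count_matrix=counts,
        modal_assignment=modal,
        mean_weights=weight_sum / n_iter,
        cluster_ages=cluster_ages,
        jaccard=jac,
        sample_ids=list(data.sample_ids),
        feature_names=list(data.feature_names),
        k=k,
        min_count=min_count,
    )


def _jaccard_from_counts(counts: np.ndarray, min_count: int) -> np.ndarray:
    k = counts.shape[1]
    members = [set(np.where(counts[:, c] >= min_count)[0]) for c in range(k)]
    jac = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            union = members[a] | members[b]
            jac[a, b] = len(members[a] & members[b]) / len(union) if union else 0.0
    return jac


def jaccard_matrix(consensus: ConsensusResult, min_count: int | None = None) -> np.ndarray:
    """Jaccard similarity between cluster membership sets.

    A sample is a member of cluster ``c`` if it was assigned there at least
    ``min_count`` times over the consensus runs; ``J(a, b) = |A & B| / |A | B|``
    with an empty union defined as 0.
    """
    if min_count is None:
        min_count = consensus.min_count
    if not 1 <= min_count <= consensus.n_iter:
        raise ParameterError(f"min_count must lie in 1..n_iter={consensus.n_iter}")
    return _jaccard_from_counts(consensus.count_matrix, min_count)


# ---------------------------------------------------------------------------
# age-randomisation null
# ---------------------------------------------------------------------------

@dataclass
class AgeRandomizationNull:
    observed_progression: float
    null_progression: np.ndarray
    p_value: float
    observed_iqr: np.ndarray  # per-cluster age IQR under true ages
    null_iqr: np.ndarray  # (n_iter, k) per-cluster age IQR under permuted ages
    n_iter: int
    degenerate: bool  # n_iter too small for a meaningful null


def _progression_stat(assignments: np.ndarray, ages: np.ndarray, k: int) -> float:
    """Spearman correlation, across samples, between age and the
    age-ordered rank of the sample's cluster.  The same cluster ordering is
    applied to observed and permuted age vectors, so ordering-induced bias
    cancels in the permutation comparison."""
    aligned = relabel_by_age(assignments, ages, k)
    rho = spearmanr(ages, aligned).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def _cluster_iqrs(assignments: np.ndarray, ages: np.ndarray, k: int) -> np.ndarray:
    aligned = relabel_by_age(assignments, ages, k)
    out = np.full(k, np.nan)
    for c in range(1, k + 1):
        a = ages[aligned == c]
        if a.size:
            out[c - 1] = float(np.subtract(*np.percentile(a, [75, 25])))
    return out


def age_randomization_null(
    data: ExpressionDataset,
    k: int,
    l1_bound: float,
    alpha: float = 0.1,
    n_iter: int = 100,
    seed: int | np.random.SeedSequence = 0,
    n_starts: int = 10,
    standardize: bool = True,
) -> AgeRandomizationNull:
    """Permutation null for the age progression of the clusters.

    Ages never enter the clustering itself, so each iteration re-clusters
    the expression matrix from a fresh start, permutes the ages over
    samples, and records the progression statistic and per-cluster age IQRs
    under the permuted ages.  The observed statistic comes from a reference
    clustering with the true ages; the empirical p-value is
    ``(1 + #{null >= observed}) / (n_iter + 1)``.
    """
    ages = data.ages
    if np.ptp(ages) == 0:
        raise DegenerateDataError("ages are constant: age progression is undefined")
    if n_iter < 1:
        raise ParameterError("n_iter must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ref_seed, perm_seed, *children = ss.spawn(n_iter + 2)
    rng = np.random.default_rng(perm_seed)

    ref = robust_sparse_kmeans(
        data, k, l1_bound, alpha=alpha, n_starts=n_starts, seed=ref_seed, standardize=standardize
    )
    observed = _progression_stat(ref.assignments, ages, k)
    observed_iqr = _cluster_iqrs(ref.assignments, ages, k)

    null_stats = np.empty(n_iter)
    null_iqr = np.empty((n_iter, k))
    for i, child in enumerate(children):
        res = robust_sparse_kmeans(
            data, k, l1_bound, alpha=alpha, n_starts=n_starts, seed=child, standardize=standardize
        )
        perm_ages = rng.permutation(ages)
        null_stats[i] = _progression_stat(res.assignments, perm_ages, k)
        null_iqr[i] = _cluster_iqrs(res.assignments, perm_ages, k)

    p = (1 + int(np.sum(null_stats >= observed))) / (n_iter + 1)
    return AgeRandomizationNull(
        observed_progression=observed,
        null_progression=null_stats,
        p_value=float(p),
        observed_iqr=observed_iqr,
        null_iqr=null_iqr,
        n_iter=n_iter,
        degenerate=n_iter < 20,
    )
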
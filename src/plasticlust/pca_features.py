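"""PCA quality-of-representation, agreement with cluster weights, and the
construction of composite "plasticity phenotype" features.

The cos2 (squared normalised coordinate) of a feature on a principal
dimension measures how well that dimension represents the feature; summed
over the first few dimensions it plays the same role for PCA that the
adaptive weight plays for sparse clustering, and the two are compared by
Spearman correlation and Bland-Altman limits of agreement.

Composite features are built from the PCA basis vectors: same-sign
high-amplitude loadings on a dimension suggest a protein *sum*, and
opposite-sign pairs suggest a two-sided *index* ``(A - B) / (A + B)`` that
captures the balance between two protein groups.  Candidates are validated
by Bonferroni-corrected correlation against the PC scores, and the
validated features summarised per cluster in a phenotype table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, spearmanr, t as t_dist

from .dataset import ExpressionDataset, zscore
from .errors import ParameterError

__all__ = [
    "PCADecomposition",
    "pca_cos2",
    "AgreementReport",
    "weight_cos2_agreement",
    "CandidateFeature",
    "propose_candidate_features",
    "compute_feature_values",
    "validate_features",
    "PhenotypeTable",
    "phenotype_table",
]


# ---------------------------------------------------------------------------
# PCA cos2
# ---------------------------------------------------------------------------

@dataclass
class PCADecomposition:
    """Correlation-PCA of the expression matrix, feature-centric view.

    ``basis_vectors`` are the unit loadings (p x d), ``scores`` the sample
    coordinates (n x d), ``cos2[j, d]`` the squared variable coordinate
    normalised by the feature's total squared coordinate over *all*
    dimensions (so each feature's cos2 over all dims sums to 1), and
    ``cos2_sum`` the per-feature sum over the retained dimensions.
    """

    basis_vectors: np.ndarray
    scores: np.ndarray
    variance_fraction: np.ndarray
    cos2: np.ndarray
    cos2_sum: np.ndarray
    feature_names: list[str]
    n_dims: int
    eigenvalues: np.ndarray

    def cos2_frame(self) -> pd.DataFrame:
        cols = [f"dim{d + 1}" for d in range(self.n_dims)]
        out = pd.DataFrame(self.cos2, index=self.feature_names, columns=cols)
        out["sum"] = self.cos2_sum
        return out


def pca_cos2(data, n_dims: int = 3, standardize: bool = True) -> PCADecomposition:
    """PCA with the cos2 quality-of-representation per feature.

    Variable coordinates are ``loading * sqrt(eigenvalue)``;
    ``cos2[j, d] = coord[j, d]^2 / sum_d' coord[j, d']^2`` with the sum over
    every available dimension (rank of the centred matrix).
    """
    if isinstance(data, ExpressionDataset):
        X = data.values
        names = list(data.feature_names)
    else:
        X = np.asarray(data, dtype=float)
        names = [f"f{j}" for j in range(X.shape[1])]
    n, p = X.shape
    rank = min(n - 1, p)
    if not 1 <= n_dims <= rank:
        raise ParameterError(f"n_dims must lie in 1..rank={rank}, got {n_dims}")
    Xc = zscore(X) if standardize else X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    S = S[:rank]
    U = U[:, :rank]
    Vt = Vt[:rank]
    eigenvalues = S**2 / (n - 1)
    coords = Vt.T * np.sqrt(eigenvalues)  # p x rank variable coordinates
    denom = (coords**2).sum(axis=1)
    denom = np.where(denom > 0, denom, 1.0)
    cos2_all = coords**2 / denom[:, None]
    total_var = eigenvalues.sum()
    return PCADecomposition(
        basis_vectors=Vt.T[:, :n_dims],
        scores=(U * S)[:, :n_dims],
        variance_fraction=eigenvalues[:n_dims] / total_var,
        cos2=cos2_all[:, :n_dims],
        cos2_sum=cos2_all[:, :n_dims].sum(axis=1),
        feature_names=names,
        n_dims=n_dims,
        eigenvalues=eigenvalues,
    )


# ---------------------------------------------------------------------------
# weights vs cos2 agreement
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Spearman + Bland-Altman agreement of cluster weights and PCA cos2.

    Both vectors are normalised by their own maximum before differencing;
    ``differences`` are weight - cos2 per feature.  Limits of agreement are
    ``mean +/- 1.96 SD`` with t-based 95% CIs.
    """

    spearman_rho: float
    spearman_p: float
    differences: pd.Series
    mean_difference: float
    mean_ci: tuple[float, float]
    loa_lower: float
    loa_upper: float
    loa_lower_ci: tuple[float, float]
    loa_upper_ci: tuple[float, float]
    outside: list[str]


def weight_cos2_agreement(mean_weights, cos2_sum, feature_names: list[str] | None = None) -> AgreementReport:
    """Compare per-feature clustering weights with PCA cos2 sums.

    Reports Spearman's rho on the raw vectors, then a Bland-Altman analysis
    of the max-normalised vectors: mean difference with 95% CI, limits of
    agreement ``mean +/- 1.96 SD`` with their 95% CIs, and the features
    falling outside the limits.
    """
    w = np.asarray(mean_weights, dtype=float)
    c = np.asarray(cos2_sum, dtype=float)
    if w.shape != c.shape or w.ndim != 1:
        raise ParameterError("inputs must be 1-D vectors of equal length")
    p = w.size
    if p < 3:
        raise ParameterError("need at least 3 features")
    if np.ptp(w) == 0 or np.ptp(c) == 0:
        raise ParameterError("constant vector: rank correlation undefined")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(p)]

    rho = spearmanr(w, c)
    wn = w / w.max()
    cn = c / c.max()
    d = wn - cn
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    tq = float(t_dist.ppf(0.975, p - 1))
    se_mean = sd_d / np.sqrt(p)
    mean_ci = (mean_d - tq * se_mean, mean_d + tq * se_mean)
    loa_lo = mean_d - 1.96 * sd_d
    loa_hi = mean_d + 1.96 * sd_d
    se_loa = sd_d * np.sqrt(1.0 / p + 1.96**2 / (2 * (p - 1)))
    loa_lo_ci = (loa_lo - tq * se_loa, loa_lo + tq * se_loa)
    loa_hi_ci = (loa_hi - tq * se_loa, loa_hi + tq * se_loa)
    outside = [feature_names[j] for j in range(p) if d[j] < loa_lo or d[j] > loa_hi]
    return AgreementReport(
        spearman_rho=float(rho.statistic),
        spearman_p=float(rho.pvalue),
        differences=pd.Series(d, index=feature_names),
        mean_difference=mean_d,
        mean_ci=mean_ci,
        loa_lower=loa_lo,
        loa_upper=loa_hi,
        loa_lower_ci=loa_lo_ci,
        loa_upper_ci=loa_hi_ci,
        outside=outside,
    )


# ---------------------------------------------------------------------------
# candidate features
# ---------------------------------------------------------------------------

@dataclass
class CandidateFeature:
    """A composite feature: a protein sum or a two-sided balance index.

    ``kind="sum"``: value = sum of ``members_a`` expression per sample.
    ``kind="index"``: value = (A - B) / (A + B) where A, B are the summed
    expressions of ``members_a`` and ``members_b``; in [-1, 1] for
    non-negative expression, +1 favouring side A entirely.
    """

    name: str
    kind: str
    members_a: list[str]
    members_b: list[str] = field(default_factory=list)
    source_dim: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("sum", "index"):
            raise ParameterError(f"kind must be 'sum' or 'index', got {self.kind!r}")
        if not self.members_a:
            raise ParameterError("members_a must be non-empty")
        if self.kind == "sum" and self.members_b:
            raise ParameterError("a sum feature takes no members_b")
        if self.kind == "index" and not self.members_b:
            raise ParameterError("an index feature needs both sides")


def propose_candidate_features(
    pca: PCADecomposition,
    cos2_cutoff: float = 0.5,
    amplitude_quantile: float = 0.7,
    pairing_rules: list[dict] | list[CandidateFeature] | None = None,
    min_group: int = 2,
) -> list[CandidateFeature]:
    """Derive candidate sums and indices from the PCA basis vectors.

    Only features whose summed cos2 exceeds ``cos2_cutoff`` are eligible.
    Per dimension, eligible features whose |loading| reaches the
    ``amplitude_quantile`` of eligible |loadings| form the high-amplitude
    set; same-sign groups of at least ``min_group`` become a sum candidate
    and opposite-sign groups become an index candidate.  ``pairing_rules``
    pins expert-chosen combinations (semi-supervised use): entries may be
    :class:`CandidateFeature` or dicts of its fields, and replace any
    auto-proposal with the same name.
    """
    if not 0 < cos2_cutoff < 1:
        raise ParameterError("cos2_cutoff must lie in (0, 1)")
    if not 0 < amplitude_quantile < 1:
        raise ParameterError("amplitude_quantile must lie in (0, 1)")
    eligible = np.where(pca.cos2_sum > cos2_cutoff)[0]
    out: list[CandidateFeature] = []
    if eligible.size == 0:
        warnings.warn("no feature exceeds the cos2 cutoff; no candidates proposed", stacklevel=2)
    else:
        for d in range(pca.n_dims):
            amps = pca.basis_vectors[eligible, d]
            thr = np.quantile(np.abs(amps), amplitude_quantile)
            high = eligible[np.abs(amps) >= thr]
            if high.size == 0:
                continue
            loads = pca.basis_vectors[high, d]
            pos = [pca.feature_names[j] for j, l in zip(high, loads) if l > 0]
            neg = [pca.feature_names[j] for j, l in zip(high, loads) if l < 0]
            if len(pos) >= min_group:
                out.append(CandidateFeature(f"dim{d + 1}_pos_sum", "sum", pos, source_dim=d + 1))
            if len(neg) >= min_group:
                out.append(CandidateFeature(f"dim{d + 1}_neg_sum", "sum", neg, source_dim=d + 1))
            if pos and neg:
                out.append(CandidateFeature(f"dim{d + 1}_index", "index", pos, neg, source_dim=d + 1))
    if pairing_rules:
        pinned = [
            rule if isinstance(rule, CandidateFeature) else CandidateFeature(**rule)
            for rule in pairing_rules
        ]
        names = {f.name for f in pinned}
        out = [f for f in out if f.name not in names] + pinned
    return out


def compute_feature_values(data, feature: CandidateFeature) -> np.ndarray:
    """Per-sample value of a composite feature on raw expression.

    Sum: the summed member expression.  Index: ``(A - B) / (A + B)``; where
    ``A + B = 0`` the index is undefined and emitted as NaN.
    """
    if isinstance(data, ExpressionDataset):
        frame = data.to_frame()
    else:
        raise ParameterError("compute_feature_values needs an ExpressionDataset")
    missing = [m for m in feature.members_a + feature.members_b if m not in frame.columns]
    if missing:
        raise ParameterError(f"feature {feature.name!r} references unknown members {missing}")
    a = frame[feature.members_a].sum(axis=1).to_numpy(float)
    if feature.kind == "sum":
        return a
    b = frame[feature.members_b].sum(axis=1).to_numpy(float)
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        idx = np.where(denom != 0, (a - b) / np.where(denom != 0, denom, 1.0), np.nan)
    return idx


def validate_features(
    data,
    features: list[CandidateFeature],
    pca: PCADecomposition,
    alpha: float = 0.05,
    n_dims: int = 3,
) -> tuple[list[CandidateFeature], pd.DataFrame]:
    """Keep candidates that correlate with at least one PC score vector.

    Pearson correlation of each feature's per-sample values against each of
    the first ``n_dims`` PC scores, Bonferroni-corrected over
    ``len(features) * n_dims`` tests at family level ``alpha``.  Returns the
    retained features and the full correlation table.
    """
    if not features:
        raise ParameterError("features must be non-empty")
    n = data.n_samples if isinstance(data, ExpressionDataset) else np.asarray(data).shape[0]
    if n < 4:
        raise ParameterError("need at least 4 samples for a correlation test")
    n_dims = min(n_dims, pca.n_dims)
    n_tests = len(features) * n_dims
    cutoff = alpha / n_tests
    rows = []
    retained: list[CandidateFeature] = []
    for f in features:
        vals = compute_feature_values(data, f)
        keep_any = False
        for d in range(n_dims):
            score = pca.scores[:, d]
            ok = np.isfinite(vals)
            if ok.sum() < 4 or np.ptp(vals[ok]) == 0:
                r, pval = np.nan, 1.0
            else:
                r, pval = pearsonr(vals[ok], score[ok])
            sig = bool(pval < cutoff)
            keep_any |= sig
            rows.append(
                {"feature": f.name, "dim": d + 1, "r": float(r), "p": float(pval), "significant": sig}
            )
        if keep_any:
            retained.append(f)
    table = pd.DataFrame(rows)
    return retained, table


# ---------------------------------------------------------------------------
# phenotype table
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Median composite-feature expression per age-ordered cluster.

    Sum-kind rows share one scale anchored at [0, max median over all sum
    features]; index-kind rows are anchored at [-1, +1].  Rows are ordered
    by average-linkage clustering of the feature-feature correlation
    matrix; ``flags`` carries the over/under ORA calls for the features.
    """

    medians: pd.DataFrame
    scale_kind: pd.Series
    flags: pd.DataFrame | None
    sum_scale_max: float
    row_order: list[str]


def phenotype_table(
    data: ExpressionDataset,
    assignments: np.ndarray,
    features: list[CandidateFeature],
    ora_table=None,
) -> PhenotypeTable:
    """Summarise validated features per cluster as the phenotype table."""
    if not features:
        raise ParameterError("features must be non-empty")
    assignments = np.asarray(assignments, dtype=int)
    k = int(assignments.max())
    sizes = np.bincount(assignments, minlength=k + 1)[1:]
    if np.any(sizes == 0):
        empty = [i + 1 for i, s in enumerate(sizes) if s == 0]
        raise ParameterError(f"clusters {empty} are empty")
    import string

    letters = list(string.ascii_uppercase[:k])
    values = {f.name: compute_feature_values(data, f) for f in features}
    med = pd.DataFrame(
        {
            letters[c - 1]: {
                name: float(np.nanmedian(v[assignments == c])) for name, v in values.items()
            }
            for c in range(1, k + 1)
        }
    )
    kinds = pd.Series({f.name: f.kind for f in features})
    sum_rows = kinds[kinds == "sum"].index
    sum_max = float(med.loc[sum_rows].max().max()) if len(sum_rows) else 0.0

    # row order from average-linkage clustering of 1 - Pearson r distances
    names = list(values)
    if len(names) > 2:
        mat = np.column_stack([values[n] for n in names])
        ok = np.all(np.isfinite(mat), axis=1)
        corr = np.corrcoef(mat[ok].T)
        corr = np.nan_to_num(corr, nan=0.0)
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        order = [names[i] for i in leaves_list(average(squareform(dist, checks=False)))]
    else:
        order = names

    flags = None
    if ora_table is not None:
        flags = ora_table.calls.reindex(index=order, columns=letters)
    return PhenotypeTable(
        medians=med.loc[order],
        scale_kind=kinds.loc[order],
        flags=flags,
        sum_scale_max=sum_max,
        row_order=order,
    )
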
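"""Lifespan trajectories and cross-omics pair correlations.

LOESS here is a local polynomial (default quadratic) regression with
tricube weights over the ``span`` nearest neighbours.  Because the fit at
any point is a linear function of the responses, pointwise standard errors
follow from the smoother weights, giving the 95% confidence band.

Protein-gene coupling across the lifespan is measured on six age bins
(<1, 1-5, 5-12, 12-20, 20-55, >55 years): each feature is z-scored within
its dataset, samples are binned, and each protein-gene pair is correlated
across the six bin means.  The summary reports the mean and median pair
correlation with a bootstrap 95% CI of the median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, t as t_dist

from .dataset import ExpressionDataset, zscore
from .errors import DegenerateDataError, ParameterError

__all__ = [
    "AgeBins",
    "LoessFit",
    "loess_trajectory",
    "PairCorrelations",
    "pair_correlations",
    "probe_to_gene",
]


@dataclass
class AgeBins:
    """Six lifespan bins: <1, 1-5, 5-12, 12-20, 20-55, >55 years.

    Bins are right-open at the printed boundaries ([1, 5) etc.) and
    partition (0, inf): every positive age maps to exactly one bin.
    """

    edges: np.ndarray = field(default_factory=lambda: np.array([1.0, 5.0, 12.0, 20.0, 55.0]))

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1

    @property
    def labels(self) -> list[str]:
        e = self.edges
        labs = [f"<{e[0]:g}"]
        labs += [f"{e[i]:g}-{e[i + 1]:g}" for i in range(len(e) - 1)]
        labs.append(f">{e[-1]:g}")
        return labs

    def assign(self, ages: np.ndarray) -> np.ndarray:
        ages = np.asarray(ages, dtype=float)
        if np.any(ages <= 0):
            raise ParameterError("ages must be strictly positive")
        return np.digitize(ages, self.edges, right=False)


# ---------------------------------------------------------------------------
# LOESS
# ---------------------------------------------------------------------------

@dataclass
class LoessFit:
    grid: np.ndarray  # ages the curve is evaluated at
    fitted: np.ndarray
    se: np.ndarray
    lower: np.ndarray  # 95% band
    upper: np.ndarray
    span: float
    degree: float
    residual_sd: float


def _local_fit_row(x: np.ndarray, x0: float, q: int, degree: int) -> np.ndarray:
    """Smoother row l(x0): fitted(x0) = l(x0) . y."""
    d = np.abs(x - x0)
    h = np.sort(d)[q - 1]
    if h == 0:
        h = max(d.max(), 1e-12) * 1e-6
    u = np.clip(d / h, 0.0, 1.0)
    w = (1 - u**3) ** 3
    active = w > 0
    if active.sum() <= degree:
        raise ParameterError("span too small: a local neighbourhood has too few points")
    B = np.vander(x - x0, degree + 1, increasing=True)  # columns 1, (x-x0), ...
    Bw = B * w[:, None]
    G = B.T @ Bw
    try:
        coef_rows = np.linalg.solve(G, Bw.T)
    except np.linalg.LinAlgError:
        coef_rows = np.linalg.pinv(G) @ Bw.T
    return coef_rows[0]  # intercept row evaluates the fit at x0


def loess_trajectory(
    values: np.ndarray,
    ages: np.ndarray,
    span: float = 0.75,
    degree: int = 2,
    grid: np.ndarray | int = 100,
    log_age: bool = False,
    conf_level: float = 0.95,
) -> LoessFit:
    """Locally weighted polynomial fit of expression over age with a
    pointwise confidence band.

    ``span`` is the fraction of samples in each local neighbourhood;
    ``log_age=True`` fits on the log-age axis (appropriate for lifespan
    data whose dynamics concentrate early) while reporting the grid in
    years.  The band is ``fit +/- t * se`` with the residual SD estimated
    from the fit at the sample points.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if y.shape != a.shape or y.ndim != 1:
        raise ParameterError("values and ages must be 1-D and equal length")
    n = y.size
    if n < 10:
        raise ParameterError(f"need at least 10 samples, got {n}")
    if np.any(a <= 0):
        raise ParameterError("ages must be strictly positive")
    q = int(np.ceil(span * n))
    if q <= degree + 1:
        raise ParameterError(f"span {span} too small for degree {degree} with n={n}")
    x = np.log(a) if log_age else a
    if isinstance(grid, int):
        grid_ages = (
            np.exp(np.linspace(np.log(a.min()), np.log(a.max()), grid))
            if log_age
            else np.linspace(a.min(), a.max(), grid)
        )
    else:
        grid_ages = np.asarray(grid, dtype=float)
    gx = np.log(grid_ages) if log_age else grid_ages

    # residual variance from the smoother at the sample points
    L = np.vstack([_local_fit_row(x, xi, q, degree) for xi in x])
    fitted_at_x = L @ y
    df = n - 2 * np.trace(L) + np.trace(L @ L.T)
    df = max(df, 1.0)
    sigma2 = float(((y - fitted_at_x) ** 2).sum() / df)

    rows = np.vstack([_local_fit_row(x, xi, q, degree) for xi in gx])
    fit = rows @ y
    se = np.sqrt(sigma2 * (rows**2).sum(axis=1))
    tq = float(t_dist.ppf(0.5 + conf_level / 2, df))
    return LoessFit(
        grid=grid_ages,
        fitted=fit,
        se=se,
        lower=fit - tq * se,
        upper=fit + tq * se,
        span=span,
        degree=degree,
        residual_sd=float(np.sqrt(sigma2)),
    )


# ---------------------------------------------------------------------------
# pair correlations
# ---------------------------------------------------------------------------

@dataclass
class PairCorrelations:
    per_pair: pd.DataFrame  # columns: protein, gene, r
    mean_r: float
    median_r: float
    median_ci: tuple[float, float]
    n_boot: int
    bins: AgeBins


def _binned_means(data: ExpressionDataset, bins: AgeBins, which: str) -> pd.DataFrame:
    """Bin x feature means of z-scored expression; errors on an empty bin."""
    z = zscore(data.values)
    idx = bins.assign(data.ages)
    out = np.empty((bins.n_bins, data.n_features))
    for b in range(bins.n_bins):
        mask = idx == b
        if not mask.any():
            raise ParameterError(
                f"age bin '{bins.labels[b]}' is empty in the {which} dataset"
            )
        out[b] = z[mask].mean(axis=0)
    return pd.DataFrame(out, index=bins.labels, columns=data.feature_names)


def pair_correlations(
    protein_data: ExpressionDataset,
    gene_data: ExpressionDataset,
    pairs: dict[str, str] | list[tuple[str, str]],
    bins: AgeBins | None = None,
    n_boot: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
) -> PairCorrelations:
    """Correlate protein and gene lifespan trajectories across age bins.

    ``pairs`` maps protein feature names to gene feature names.  For each
    pair, Pearson r is computed across the six age-bin means of z-scored
    expression; the bootstrap 95% CI of the median r uses the percentile
    method.
    """
    if bins is None:
        bins = AgeBins()
    pair_list = list(pairs.items()) if isinstance(pairs, dict) else list(pairs)
    if not pair_list:
        raise ParameterError("pairs must be non-empty")
    prot_means = _binned_means(protein_data, bins, "protein")
    gene_means = _binned_means(gene_data, bins, "gene")
    rows = []
    for prot, gene in pair_list:
        if prot not in prot_means.columns:
            raise ParameterError(f"pair member {prot!r} not in the protein dataset")
        if gene not in gene_means.columns:
            raise ParameterError(f"pair member {gene!r} not in the gene dataset")
        pv = prot_means[prot].to_numpy()
        gv = gene_means[gene].to_numpy()
        if np.ptp(pv) == 0 or np.ptp(gv) == 0:
            r = np.nan
        else:
            r = float(pearsonr(pv, gv).statistic)
        rows.append({"protein": prot, "gene": gene, "r": r})
    per_pair = pd.DataFrame(rows)
    r_vals = per_pair["r"].dropna().to_numpy()
    if r_vals.size == 0:
        raise DegenerateDataError("no pair produced a defined correlation")
    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    boots = np.median(
        r_vals[rng.integers(0, r_vals.size, size=(n_boot, r_vals.size))], axis=1
    )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return PairCorrelations(
        per_pair=per_pair,
        mean_r=float(r_vals.mean()),
        median_r=float(np.median(r_vals)),
        median_ci=(float(lo), float(hi)),
        n_boot=n_boot,
        bins=bins,
    )


# ---------------------------------------------------------------------------
# probe -> gene summarisation
# ---------------------------------------------------------------------------

def probe_to_gene(
    exon_table: pd.DataFrame,
    probe_gene_map: dict[str, str] | pd.Series,
    r_threshold: float = 0.9,
    on_fail: str = "max_variance",
) -> pd.DataFrame:
    """Collapse a probe x sample exon table to gene x sample.

    Multi-probe genes whose probes all pairwise correlate at
    ``r >= r_threshold`` are averaged; single-probe genes pass through.
    Genes failing the rule are handled per ``on_fail``: ``"max_variance"``
    keeps the highest-variance probe as the gene's representative,
    ``"keep_all"`` retains every probe as a separate row tagged
    ``gene|probe``.  Probes missing from the map are dropped with a
    warning.
    """
    if not 0 < r_threshold <= 1:
        raise ParameterError("r_threshold must lie in (0, 1]")
    if on_fail not in ("max_variance", "keep_all"):
        raise ParameterError("on_fail must be 'max_variance' or 'keep_all'")
    mapping = dict(probe_gene_map) if not isinstance(probe_gene_map, pd.Series) else probe_gene_map.to_dict()
    unmapped = [pr for pr in exon_table.index if pr not in mapping]
    if unmapped:
        warnings.warn(f"dropping {len(unmapped)} unmapped probes: {unmapped[:5]}...", stacklevel=2)
    table = exon_table.loc[[pr for pr in exon_table.index if pr in mapping]]

    gene_rows: dict[str, np.ndarray] = {}
    by_gene: dict[str, list[str]] = {}
    for pr in table.index:
        by_gene.setdefault(mapping[pr], []).append(pr)
    for gene, probes in by_gene.items():
        block = table.loc[probes].to_numpy(float)
        if len(probes) == 1:
            gene_rows[gene] = block[0]
            continue
        corr = np.corrcoef(block)
        iu = np.triu_indices(len(probes), k=1)
        if np.all(corr[iu] >= r_threshold):
            gene_rows[gene] = block.mean(axis=0)
        elif on_fail == "max_variance":
            gene_rows[gene] = block[int(np.argmax(block.var(axis=1, ddof=1)))]
        else:
            for pr, row in zip(probes, block):
                gene_rows[f"{gene}|{pr}"] = row
    out = pd.DataFrame.from_dict(gene_rows, orient="index", columns=exon_table.columns)
    return out.sort_index()
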
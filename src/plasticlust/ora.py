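"""Over-representation analysis of cluster expression against a normal null.

For each feature, a normal distribution is simulated from the mean and SD
of that feature's expression over *all* samples.  A cluster is called
over-represented for the feature if the cluster's 25th percentile lies
above the simulated distribution's 95th percentile, under-represented if
the cluster's 75th percentile lies below the simulated 5th percentile, and
neutral otherwise.  The cutoffs are configurable (e.g. 99th/1st for a
stricter call), and an analytic mode replaces the Monte-Carlo quantiles by
exact normal quantiles (mean +/- 1.6449 SD at the default cutoffs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dataset import ExpressionDataset
from .errors import ParameterError

__all__ = ["ORATable", "ora_classify"]

CALL_OVER = "over"
CALL_UNDER = "under"
CALL_NEUTRAL = "neutral"


@dataclass
class ORATable:
    """Over/under/neutral call per (feature, cluster) cell.

    ``calls`` is a features x clusters DataFrame of strings; ``upper_cut``
    and ``lower_cut`` hold each feature's simulated (or analytic) null
    quantiles.
    """

    calls: pd.DataFrame
    upper_cut: pd.Series
    lower_cut: pd.Series
    n_sim: int
    sim_quantiles: tuple[float, float]
    cluster_quantiles: tuple[float, float]
    analytic: bool

    def to_long(self) -> pd.DataFrame:
        long = self.calls.stack().rename("call").reset_index()
        long.columns = ["feature", "cluster", "call"]
        long["upper_cut"] = long["feature"].map(self.upper_cut)
        long["lower_cut"] = long["feature"].map(self.lower_cut)
        return long

    def n_flagged(self) -> pd.Series:
        """Number of over- or under-represented features per cluster."""
        return (self.calls != CALL_NEUTRAL).sum(axis=0)


def ora_classify(
    data,
    assignments: np.ndarray,
    n_sim: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
    sim_quantiles: tuple[float, float] = (0.05, 0.95),
    cluster_quantiles: tuple[float, float] = (0.25, 0.75),
    analytic: bool = False,
    cluster_names: list[str] | None = None,
) -> ORATable:
    """Colour every (feature, cluster) cell over/under/neutral.

    Parameters
    ----------
    data
        :class:`ExpressionDataset` or plain (n, p) array; raw expression
        values are used (the null is built per feature from all samples).
    assignments
        1..k cluster labels per sample; every cluster needs >= 2 samples
        for a percentile to be meaningful.
    n_sim
        Monte-Carlo draws per feature (>= 1000 unless ``analytic``).
    sim_quantiles
        Null quantiles the cluster percentiles are compared against.
    cluster_quantiles
        Which cluster percentiles are compared (default quartiles).
    analytic
        Replace simulation with exact normal quantiles: deterministic and
        the ``n_sim -> inf`` limit of the Monte-Carlo procedure.

    A feature with zero SD across all samples yields neutral calls for
    every cluster (with a warning): there is no dispersion to simulate.
    """
    if isinstance(data, ExpressionDataset):
        X = data.values
        feature_names = list(data.feature_names)
    else:
        X = np.asarray(data, dtype=float)
        feature_names = [f"f{j}" for j in range(X.shape[1])]
    assignments = np.asarray(assignments, dtype=int)
    if assignments.shape[0] != X.shape[0]:
        raise ParameterError("assignments length does not match data")
    lo_q, hi_q = sim_quantiles
    c_lo, c_hi = cluster_quantiles
    if not (0 < lo_q < hi_q < 1) or not (0 < c_lo < c_hi < 1):
        raise ParameterError("quantiles must satisfy 0 < low < high < 1")
    if not analytic and n_sim < 1000:
        raise ParameterError("n_sim must be >= 1000 (or use analytic=True)")

    k = int(assignments.max())
    if assignments.min() < 1:
        raise ParameterError("labels must lie in 1..k")
    sizes = np.bincount(assignments, minlength=k + 1)[1:]
    if np.any(sizes < 2):
        small = [i + 1 for i, s in enumerate(sizes) if s < 2]
        raise ParameterError(f"clusters {small} have fewer than 2 samples")
    if cluster_names is None:
        import string

        cluster_names = list(string.ascii_uppercase[:k])

    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    p = X.shape[1]
    upper = np.empty(p)
    lower = np.empty(p)
    calls = np.full((p, k), CALL_NEUTRAL, dtype=object)
    for j in range(p):
        col = X[:, j]
        mu, sd = float(col.mean()), float(col.std(ddof=1))
        if sd == 0:
            warnings.warn(
                f"feature {feature_names[j]!r} has zero SD; all calls neutral",
                stacklevel=2,
            )
            upper[j] = lower[j] = mu
            continue
        if analytic:
            lower[j] = mu + norm.ppf(lo_q) * sd
            upper[j] = mu + norm.ppf(hi_q) * sd
        else:
            sim = rng.normal(mu, sd, size=n_sim)
            lower[j], upper[j] = np.quantile(sim, [lo_q, hi_q])  # linear interpolation
        for c in range(1, k + 1):
            vals = col[assignments == c]
            q_lo, q_hi = np.quantile(vals, [c_lo, c_hi])
            if q_lo > upper[j]:
                calls[j, c - 1] = CALL_OVER
            elif q_hi < lower[j]:
                calls[j, c - 1] = CALL_UNDER

    return ORATable(
        calls=pd.DataFrame(calls, index=feature_names, columns=cluster_names),
        upper_cut=pd.Series(upper, index=feature_names),
        lower_cut=pd.Series(lower, index=feature_names),
        n_sim=0 if analytic else n_sim,
        sim_quantiles=sim_quantiles,
        cluster_quantiles=cluster_quantiles,
        analytic=analytic,
    )
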
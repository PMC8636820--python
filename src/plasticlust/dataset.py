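"""The samples x features expression container used throughout the package.

An :class:`ExpressionDataset` holds a numeric expression matrix (one row per
tissue sample, one column per protein or gene), the age of every sample in
years, and optional per-sample annotations (sex, post-mortem interval, and a
sample -> subject map when one subject was measured in several replicate
runs).  All pipeline stages consume and produce this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataFormatError

__all__ = ["ExpressionDataset", "zscore"]


def zscore(values: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Column-wise z-score; constant columns are centred but not scaled."""
    values = np.asarray(values, dtype=float)
    mu = values.mean(axis=0)
    sd = values.std(axis=0, ddof=ddof)
    sd = np.where(sd > 0, sd, 1.0)
    return (values - mu) / sd


def trimmed_zscore(values: np.ndarray, trim_frac: float) -> np.ndarray:
    """Column-wise z-score with the most extreme *samples* (whole rows)
    trimmed from the location/scale estimates.

    Outlier samples inflate the ordinary SD of exactly the features they
    corrupt, shrinking those features' standardised signal.  Rows are
    ranked by a robust multivariate extremity score (sum of squared
    median/MAD deviations over features) and the ``ceil(trim_frac * n)``
    most extreme rows are excluded from the per-feature mean/SD; the whole
    matrix is then standardised with those estimates.  Trimming rows, not
    per-feature tails, keeps the noise/signal scale balance intact: a
    per-feature trim would truncate every noise feature's tails and
    systematically amplify noise.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    n_trim = int(np.ceil(trim_frac * n))
    if n_trim <= 0:
        return zscore(values)
    med = np.median(values, axis=0)
    mad = 1.4826 * np.median(np.abs(values - med), axis=0)
    sd_all = values.std(axis=0, ddof=1)
    scale = np.where(mad > 0, mad, np.where(sd_all > 0, sd_all, 1.0))
    extremity = (((values - med) / scale) ** 2).sum(axis=1)
    keep = np.argsort(extremity, kind="stable")[: n - n_trim]
    mu = values[keep].mean(axis=0)
    sd = values[keep].std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, np.where(sd_all > 0, sd_all, 1.0))
    return (values - mu) / sd


@dataclass
class ExpressionDataset:
    """Expression matrix with sample ages and metadata.

    Parameters
    ----------
    values
        ``(n_samples, n_features)`` float matrix, no missing values.
    feature_names
        Unique names for the ``p`` features (proteins or genes).
    sample_ids
        Unique identifiers for the ``n`` samples (replicate runs get their
        own id; ``run_of`` maps them back to subjects).
    ages
        Sample ages in years, non-negative.
    run_of
        Optional map ``sample_id -> subject_id`` for replicate runs.
    sex, pmi
        Optional per-sample annotations (biological sex, post-mortem
        interval in hours).
    """

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    ages: np.ndarray
    run_of: dict[str, str] | None = None
    sex: list[str] | None = None
    pmi: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ages = np.asarray(self.ages, dtype=float)
        self.feature_names = [str(f) for f in self.feature_names]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise DataFormatError("values must be a 2-D samples x features matrix")
        n, p = self.values.shape
        if p < 2:
            raise DataFormatError(f"need at least 2 features, got {p}")
        if len(self.feature_names) != p:
            raise DataFormatError("feature_names length does not match values")
        if len(set(self.feature_names)) != p:
            raise DataFormatError("feature_names must be unique")
        if len(self.sample_ids) != n:
            raise DataFormatError("sample_ids length does not match values")
        if len(set(self.sample_ids)) != n:
            raise DataFormatError("sample_ids must be unique")
        if self.ages.shape != (n,):
            raise DataFormatError("ages length does not match values")
        if np.any(~np.isfinite(self.values)):
            raise DataFormatError("values contain missing or non-finite entries")
        if np.any(~np.isfinite(self.ages)) or np.any(self.ages < 0):
            raise DataFormatError("ages must be finite and non-negative")

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def zscored_values(self, ddof: int = 1) -> np.ndarray:
        """Per-feature z-scored copy of the matrix."""
        return zscore(self.values, ddof=ddof)

    def feature_index(self, name: str) -> int:
        try:
            return self.feature_names.index(name)
        except ValueError as exc:
            raise KeyError(f"unknown feature {name!r}") from exc

    # -- replicate handling ---------------------------------------------
    def average_replicates(self) -> "ExpressionDataset":
        """Collapse replicate runs of one subject to the subject mean.

        Requires ``run_of``; samples without an entry are treated as their
        own subject.  Subject age is the mean of the run ages (runs of one
        post-mortem sample share an age, so this is a no-op on ages).
        """
        if not self.run_of:
            return self
        subj_of = [self.run_of.get(s, s) for s in self.sample_ids]
        order: list[str] = []
        for s in subj_of:
            if s not in order:
                order.append(s)
        idx = {s: i for i, s in enumerate(order)}
        groups = [[] for _ in order]
        for row, s in enumerate(subj_of):
            groups[idx[s]].append(row)
        values = np.vstack([self.values[g].mean(axis=0) for g in groups])
        ages = np.array([self.ages[g].mean() for g in groups])
        sex = None
        if self.sex is not None:
            sex = [self.sex[g[0]] for g in groups]
        pmi = None
        if self.pmi is not None:
            pmi = np.array([np.mean(np.asarray(self.pmi, float)[g]) for g in groups])
        return ExpressionDataset(
            values=values,
            feature_names=list(self.feature_names),
            sample_ids=order,
            ages=ages,
            run_of=None,
            sex=sex,
            pmi=pmi,
        )

    def subset_features(self, names: list[str]) -> "ExpressionDataset":
        cols = [self.feature_index(n) for n in names]
        return ExpressionDataset(
            values=self.values[:, cols],
            feature_names=list(names),
            sample_ids=list(self.sample_ids),
            ages=self.ages.copy(),
            run_of=dict(self.run_of) if self.run_of else None,
            sex=list(self.sex) if self.sex is not None else None,
            pmi=None if self.pmi is None else np.asarray(self.pmi).copy(),
        )

    # -- pandas views ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_names)

    def metadata_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame({"sample_id": self.sample_ids, "age": self.ages})
        if self.sex is not None:
            meta["sex"] = self.sex
        if self.pmi is not None:
            meta["pmi"] = self.pmi
        if self.run_of:
            meta["subject"] = [self.run_of.get(s, s) for s in self.sample_ids]
        return meta
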
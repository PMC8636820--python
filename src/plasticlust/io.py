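"""Readers and writers for the CSV/TSV formats the pipeline consumes.

An expression table is samples x features with a header row of feature
names and the sample id in the first column; the metadata table has a
``sample_id`` column, an ``age`` column in years, and optional ``sex``,
``pmi`` and ``subject`` (replicate run mapping) columns.  Separator is
inferred from the extension (``.tsv``/``.tab`` = tab, otherwise comma).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .errors import DataFormatError

__all__ = ["read_expression", "write_expression"]

_COMMA_DECIMAL = re.compile(r"^-?\d+,\d+$")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def _to_numeric(frame: pd.DataFrame, path: Path) -> pd.DataFrame:
    try:
        return frame.astype(float)
    except (TypeError, ValueError):
        pass
    for col in frame.columns:
        bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna()]
        for idx, val in bad.items():
            if isinstance(val, str) and _COMMA_DECIMAL.match(val.strip()):
                raise DataFormatError(
                    f"non-numeric cell {val!r} at sample {idx!r}, feature {col!r} in {path}: "
                    "looks like a comma decimal; re-export with '.' as the decimal separator"
                )
            raise DataFormatError(
                f"non-numeric cell {val!r} at sample {idx!r}, feature {col!r} in {path}"
            )
    raise DataFormatError(f"could not coerce {path} to a numeric matrix")


def read_expression(path, metadata_path, replicates: str = "keep") -> ExpressionDataset:
    """Read an expression table and its sample metadata into a dataset.

    ``replicates`` is ``"keep"`` or ``"average"`` (collapse replicate runs
    of one subject via the metadata ``subject`` column).
    """
    path, metadata_path = Path(path), Path(metadata_path)
    expr = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    expr.index = expr.index.astype(str)
    if expr.index.duplicated().any():
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise DataFormatError(f"duplicate sample ids in {path}: {dups}")
    if expr.columns.duplicated().any():
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise DataFormatError(f"duplicate feature names in {path}: {dups}")
    values = _to_numeric(expr, path)

    meta = pd.read_csv(metadata_path, sep=_sep_for(metadata_path))
    if "sample_id" not in meta.columns:
        raise DataFormatError(f"metadata {metadata_path} lacks a 'sample_id' column")
    if "age" not in meta.columns:
        raise DataFormatError(f"metadata {metadata_path} lacks an 'age' column (years)")
    meta["sample_id"] = meta["sample_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise DataFormatError(f"duplicate sample ids in metadata: {dups}")
    meta = meta.set_index("sample_id")
    missing = [s for s in values.index if s not in meta.index]
    if missing:
        raise DataFormatError(f"metadata is missing samples: {missing}")
    meta = meta.loc[values.index]
    ages = pd.to_numeric(meta["age"], errors="coerce")
    if ages.isna().any():
        bad = meta.index[ages.isna()].tolist()
        raise DataFormatError(f"missing or non-numeric ages for samples: {bad}")

    run_of = None
    if "subject" in meta.columns and meta["subject"].notna().any():
        run_of = {s: str(subj) for s, subj in meta["subject"].items() if pd.notna(subj)}
    ds = ExpressionDataset(
        values=values.to_numpy(float),
        feature_names=list(values.columns),
        sample_ids=list(values.index),
        ages=ages.to_numpy(float),
        run_of=run_of,
        sex=list(meta["sex"]) if "sex" in meta.columns else None,
        pmi=pd.to_numeric(meta["pmi"], errors="coerce").to_numpy() if "pmi" in meta.columns else None,
    )
    if replicates == "average":
        ds = ds.average_replicates()
    elif replicates != "keep":
        raise DataFormatError("replicates must be 'keep' or 'average'")
    return ds


def write_expression(data: ExpressionDataset, path, metadata_path) -> None:
    """Write the expression matrix and metadata back to CSV/TSV."""
    path, metadata_path = Path(path), Path(metadata_path)
    frame = data.to_frame()
    frame.index.name = "sample_id"
    frame.to_csv(path, sep=_sep_for(path))
    data.metadata_frame().to_csv(metadata_path, sep=_sep_for(metadata_path), index=False)
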
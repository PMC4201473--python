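"""Readers and writers for delimited expression/response tables.

Expression matrices are numeric TSV/CSV files with a header row of feature
IDs and a first column of sample IDs; both orientations are accepted on read
and samples-by-features is canonical internally.  Expression values must be
complete; responses may contain missing values, which are handled by
dropping the affected samples during alignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DataMatrix",
    "ResponseTable",
    "read_matrix",
    "write_matrix",
    "read_response",
    "align",
    "write_run_metadata",
]


@dataclass
class DataMatrix:
    """Sample x feature numeric matrix with unique sample and feature IDs."""

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("schema: dimensions inconsistent with ID lists")
        for name, ids in (("sample", self.sample_ids), ("feature", self.feature_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError("schema: duplicate %s IDs" % name)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("parse: expression matrix contains non-finite values")


@dataclass
class ResponseTable:
    """Per-sample responses (may contain missing values)."""

    sample_ids: list[str]
    values: np.ndarray
    response_name: str = "response"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.shape[0] != len(self.sample_ids):
            raise ValueError("schema: response length and sample IDs differ")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("schema: duplicate sample IDs")


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_matrix(path: str | Path, orientation: str = "samples-by-features") -> DataMatrix:
    """Read a delimited numeric matrix; ``features-by-samples`` input is
    transposed to the canonical orientation."""
    if orientation not in ("samples-by-features", "features-by-samples"):
        raise ValueError("unknown orientation %r" % (orientation,))
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if orientation == "features-by-samples":
        df = df.T
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError("parse: non-numeric cell in %s (%s)" % (path, exc)) from exc
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            "parse: missing/non-finite value at sample %r, feature %r in %s"
            % (df.index[i], df.columns[j], path)
        )
    return DataMatrix(values, list(df.index), list(df.columns))


def write_matrix(dm: DataMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.values, index=dm.sample_ids, columns=dm.feature_ids).to_csv(
        path, sep=_sep_for(path)
    )


def read_response(path: str | Path, column: str | None = None) -> ResponseTable:
    """Read a per-sample response table; ``column`` picks one of several
    response columns (default: the first).  Missing cells are kept as NaN."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if column is None:
        column = df.columns[0]
    if column not in df.columns:
        raise ValueError("schema: response column %r not found" % (column,))
    vals = pd.to_numeric(df[column], errors="coerce").to_numpy(dtype=float)
    return ResponseTable(list(df.index), vals, response_name=str(column))


def align(X: DataMatrix, y: ResponseTable) -> tuple[DataMatrix, np.ndarray, list[str]]:
    """Intersect by sample ID (order follows X), dropping samples whose
    response is missing.  Returns the aligned matrix, response vector and the
    IDs of dropped samples."""
    resp = dict(zip(y.sample_ids, y.values))
    keep_rows, values, dropped = [], [], []
    for i, sid in enumerate(X.sample_ids):
        v = resp.get(sid, np.nan)
        if np.isfinite(v):
            keep_rows.append(i)
            values.append(v)
        else:
            dropped.append(sid)
    if not keep_rows:
        raise ValueError("no shared samples between matrix and response")
    aligned = DataMatrix(
        X.values[keep_rows], [X.sample_ids[i] for i in keep_rows], X.feature_ids
    )
    return aligned, np.asarray(values), dropped


def write_run_metadata(path: str | Path, **metadata) -> None:
    """Sidecar JSON recording the config and seed that produced an output."""
    with open(path, "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
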
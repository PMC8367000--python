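"""Expression-matrix preprocessing: min-max scaling and mean-threshold
binarization.

The pipeline consumes an n-samples × N-genes matrix of real-valued
expression measurements (rows = lines/samples, columns = genes). Each
column is min-max scaled to [0, 1], then binarized against the mean of its
*normalized* values: a value at or above the column mean becomes 1
(activation), below it 0 (inhibition). The ≥ convention is centralised in
``BINARIZE_AT_MEAN`` so the opposite tie rule can be swapped in one place;
with ≥, the column maximum is always scored as activated.

Missing values are a hard error — the analysis assumes a complete matrix
and no imputation is performed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BinaryDataset",
    "read_expression_csv",
    "min_max_normalize",
    "binarize_by_mean",
    "activation_counts",
]

logger = logging.getLogger(__name__)

#: Tie rule at the threshold: True means value == mean maps to 1.
BINARIZE_AT_MEAN = True


@dataclass
class BinaryDataset:
    """A binarized expression matrix plus the per-column thresholds used.

    ``data`` holds {0,1} values with the same shape and column names as the
    source matrix; ``thresholds`` records each column's normalized-mean
    cutoff (may be None for data that was never continuous, e.g. forward
    samples from a ground-truth model).
    """

    data: pd.DataFrame
    thresholds: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("BinaryDataset values must all be 0 or 1")

    @property
    def n(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BinaryDataset":
        return cls(data=pd.read_csv(path).astype(np.int8))

    def thresholds_to_json(self, path: str | Path) -> None:
        if self.thresholds is None:
            raise ValueError("no thresholds recorded")
        Path(path).write_text(json.dumps(self.thresholds.round(12).to_dict(), indent=1))


def read_expression_csv(
    path: str | Path,
    name_map: str | Path | None = None,
    transpose: bool = False,
) -> pd.DataFrame:
    """Read an expression CSV (header row of identifiers, numeric body).

    ``name_map`` is an optional two-column CSV (probe_id, gene_name); when
    given, columns are renamed and any column absent from the map is dropped
    with a warning. ``transpose`` accommodates genes-as-rows exports.
    """
    df = pd.read_csv(path, index_col=0 if transpose else None)
    if transpose:
        df = df.T
        df.columns.name = None
        df = df.reset_index(drop=True).apply(pd.to_numeric)
    if df.empty:
        raise ValueError(f"{path}: empty expression matrix")
    bad = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(bad):
        raise ValueError(f"{path}: non-numeric column(s): {list(bad)}")
    if df.isna().any().any():
        r, c = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at row {r}, column {df.columns[c]!r} "
            "(no imputation is performed)"
        )
    if name_map is not None:
        mp = pd.read_csv(name_map)
        mapping = dict(zip(mp.iloc[:, 0].astype(str), mp.iloc[:, 1].astype(str)))
        dropped = [c for c in df.columns if c not in mapping]
        if dropped:
            logger.warning("dropping %d unmapped column(s): %s", len(dropped), dropped)
        df = df[[c for c in df.columns if c in mapping]].rename(columns=mapping)
    if df.columns.duplicated().any():
        dupes = sorted(set(df.columns[df.columns.duplicated()]))
        raise ValueError(f"duplicate column name(s) after mapping: {dupes}")
    return df


def min_max_normalize(mat: pd.DataFrame) -> pd.DataFrame:
    """Per-column min-max scaling: x ↦ (x − min)/(max − min).

    Every output column attains both 0 and 1. A constant column is an error
    (the scale is undefined and no safe default exists).
    """
    lo = mat.min(axis=0)
    hi = mat.max(axis=0)
    constant = mat.columns[(hi - lo) == 0]
    if len(constant):
        raise ValueError(f"constant column(s), min-max scale undefined: {list(constant)}")
    return (mat - lo) / (hi - lo)


def binarize_by_mean(mat: pd.DataFrame) -> BinaryDataset:
    """Threshold each normalized column at its own mean (≥ mean → 1)."""
    vals = mat.to_numpy(dtype=float)
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("binarize_by_mean expects a normalized matrix in [0, 1]")
    thresholds = mat.mean(axis=0)
    if BINARIZE_AT_MEAN:
        binary = (mat >= thresholds).astype(np.int8)
    else:
        binary = (mat > thresholds).astype(np.int8)
    return BinaryDataset(data=binary, thresholds=thresholds)


def activation_counts(data: BinaryDataset) -> pd.DataFrame:
    """Per-node activation (1) and inhibition (0) counts; rows sum to n.

    This is the tabular form of the activation-vs-inhibition bar plot over
    the processed dataset.
    """
    active = data.data.sum(axis=0).astype(int)
    return pd.DataFrame(
        {"active": active, "inactive": data.n - active},
        index=data.data.columns,
    )
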
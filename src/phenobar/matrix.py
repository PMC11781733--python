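"""FeatureMatrix: the common carrier for descriptor tables and barcode tables.

Rows are compounds, columns are numeric features (chemical descriptors,
fingerprint bits, or behavioral barcode entries).  Missing values are NaN in
memory and the token ``NA`` on disk.  An optional ``CLASS`` column carries the
functional class code (1-4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .compounds import ClassLabel
from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

PROVENANCES = ("chemical_2d", "chemical_3d", "behavioral")


@dataclass
class FeatureMatrix:
    row_ids: list[str]
    column_names: list[str]
    values: np.ndarray
    class_labels: list[ClassLabel] | None = None
    provenance: str = "behavioral"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.column_names)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.column_names)} columns")
        if len(set(self.column_names)) != len(self.column_names):
            raise ValidationError("column names must be unique")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValidationError("row ids must be unique")
        if self.class_labels is not None and len(self.class_labels) != len(self.row_ids):
            raise ValidationError("class_labels must align with row_ids")
        if self.provenance not in PROVENANCES:
            raise ValidationError(f"unknown provenance {self.provenance!r}")

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_columns(self) -> int:
        return len(self.column_names)

    def select_columns(self, names: Sequence[str]) -> "FeatureMatrix":
        idx = [self.column_names.index(n) for n in names]
        return replace(self, column_names=list(names), values=self.values[:, idx])

    def select_rows(self, ids: Sequence[str]) -> "FeatureMatrix":
        idx = [self.row_ids.index(i) for i in ids]
        labels = [self.class_labels[i] for i in idx] if self.class_labels else None
        return replace(self, row_ids=list(ids), values=self.values[idx], class_labels=labels)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.row_ids, columns=self.column_names)
        df.index.name = "id"
        return df


def write_feature_matrix(m: FeatureMatrix, path: str | Path) -> None:
    """Write to CSV; values keep 12 significant digits, missing becomes NA."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        cols = ["id"] + (["CLASS"] if m.class_labels is not None else []) + m.column_names
        fh.write(",".join(cols) + "\n")
        for i, rid in enumerate(m.row_ids):
            cells = [rid]
            if m.class_labels is not None:
                cells.append(str(m.class_labels[i].code))
            cells += ["NA" if np.isnan(v) else f"{v:.12g}" for v in m.values[i]]
            fh.write(",".join(cells) + "\n")


def read_feature_matrix(path: str | Path, provenance: str = "behavioral") -> FeatureMatrix:
    """Read a CSV whose first column is row IDs, with an optional CLASS column.

    Non-numeric cells outside CLASS are recorded as missing with a warning.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 1:
        raise FormatError(f"{path}: empty table")
    id_col = df.columns[0]
    row_ids = df[id_col].tolist()
    if len(set(row_ids)) != len(row_ids):
        raise FormatError(f"{path}: duplicate row IDs")
    labels = None
    if "CLASS" in df.columns:
        labels = [ClassLabel.from_code(int(c)) for c in df["CLASS"]]
    feat_cols = [c for c in df.columns if c not in (id_col, "CLASS")]
    values = np.empty((len(row_ids), len(feat_cols)))
    n_bad = 0
    for j, c in enumerate(feat_cols):
        col = pd.to_numeric(df[c].mask(df[c].isin(["NA", ""])), errors="coerce")
        bad = col.isna() & ~df[c].isin(["NA", ""])
        n_bad += int(bad.sum())
        values[:, j] = col.to_numpy()
    if n_bad:
        log.warning("%s: %d non-numeric cells recorded as missing", path, n_bad)
    return FeatureMatrix(row_ids=row_ids, column_names=feat_cols, values=values,
                         class_labels=labels, provenance=provenance)
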
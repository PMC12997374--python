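"""Tabular clinical dataset container.

The container mirrors the layout of the public chronic-kidney-disease
screening table: a mix of nominal and numeric attributes with an explicit
missing marker ("?" in the CSV dialect), plus a binary class label
(1 = CKD, 0 = not CKD).  Nominal columns carry their allowed category set
so that downstream domain validation can reject implausible entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_TOKEN = "?"

NUMERIC = "numeric"
NOMINAL = "nominal"


@dataclass(frozen=True)
class ColumnMeta:
    """Schema of one attribute column."""

    name: str
    kind: str  # NUMERIC or NOMINAL
    categories: tuple[str, ...] = ()  # allowed set, nominal columns only

    def __post_init__(self) -> None:
        if self.kind not in (NUMERIC, NOMINAL):
            raise ValueError(f"unknown column kind {self.kind!r}")
        if self.kind == NOMINAL and not self.categories:
            raise ValueError(f"nominal column {self.name!r} needs categories")


@dataclass
class TabularDataset:
    """Feature table with per-column metadata, binary labels and provenance.

    ``X`` holds numeric columns as float (NaN = missing) and nominal
    columns as object dtype (None/NaN = missing).  ``synthetic`` flags rows
    created by oversampling so they can never leak into evaluation splits.
    ``informative_idx`` records the planted ground-truth feature set on
    simulated fixtures; it is ``None`` on real data.
    """

    X: pd.DataFrame
    col_meta: list[ColumnMeta]
    y: np.ndarray
    informative_idx: frozenset[int] | None = None
    synthetic: np.ndarray = field(default=None)  # type: ignore[assignment]
    # for encoded (one-hot) views: original feature index of each column
    origin: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        if len(self.col_meta) != self.X.shape[1]:
            raise ValueError("col_meta length must match number of columns")
        if len(self.y) != len(self.X):
            raise ValueError("labels length must match number of rows")
        if not np.isin(self.y, [0, 1]).all():
            raise ValueError("labels must be binary")
        if self.synthetic is None:
            self.synthetic = np.zeros(len(self.X), dtype=bool)
        else:
            self.synthetic = np.asarray(self.synthetic, dtype=bool)

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return [c.name for c in self.col_meta]

    def numeric_columns(self) -> list[str]:
        return [c.name for c in self.col_meta if c.kind == NUMERIC]

    def nominal_columns(self) -> list[str]:
        return [c.name for c in self.col_meta if c.kind == NOMINAL]

    def missing_mask(self) -> pd.DataFrame:
        return self.X.isna()

    def copy(self) -> "TabularDataset":
        return TabularDataset(
            X=self.X.copy(),
            col_meta=list(self.col_meta),
            y=self.y.copy(),
            informative_idx=self.informative_idx,
            synthetic=self.synthetic.copy(),
            origin=self.origin,
        )

    def subset(self, idx) -> "TabularDataset":
        """Row subset by positional index, preserving metadata."""
        idx = np.asarray(idx)
        return TabularDataset(
            X=self.X.iloc[idx].reset_index(drop=True),
            col_meta=list(self.col_meta),
            y=self.y[idx],
            informative_idx=self.informative_idx,
            synthetic=self.synthetic[idx],
            origin=self.origin,
        )

    # -- CSV dialect ----------------------------------------------------
    def to_csv(self, path, label_name: str = "class",
               labels: tuple[str, str] = ("notckd", "ckd")) -> None:
        """Write the UCI dialect: '?' marks missing, label column last."""
        out = self.X.copy()
        for c in self.col_meta:
            col = out[c.name]
            if c.kind == NUMERIC:
                out[c.name] = col.map(
                    lambda v: MISSING_TOKEN if pd.isna(v) else repr(float(v))
                )
            else:
                out[c.name] = col.map(
                    lambda v: MISSING_TOKEN if pd.isna(v) else str(v)
                )
        out[label_name] = [labels[int(v)] for v in self.y]
        out.to_csv(path, index=False)


def read_uci_csv(path, col_meta: list[ColumnMeta], label_name: str = "class",
                 positive_label: str = "ckd") -> TabularDataset:
    """Read a UCI-dialect CSV ('?' = missing) against a known schema."""
    raw = pd.read_csv(path, dtype=str, na_values=[MISSING_TOKEN],
                      skipinitialspace=True)
    if label_name not in raw.columns:
        raise ValueError(f"label column {label_name!r} missing from {path}")
    X = pd.DataFrame(index=raw.index)
    for c in col_meta:
        if c.name not in raw.columns:
            raise ValueError(f"column {c.name!r} missing from {path}")
        if c.kind == NUMERIC:
            X[c.name] = pd.to_numeric(raw[c.name], errors="coerce")
        else:
            X[c.name] = raw[c.name].astype(object)
    lab = raw[label_name].astype(str).str.strip()
    y = (lab == positive_label).astype(np.int8).to_numpy()
    return TabularDataset(X=X, col_meta=list(col_meta), y=y)


def uci_ckd_schema() -> list[ColumnMeta]:
    """The 24-attribute schema of the public CKD screening table."""
    sg = ("1.005", "1.010", "1.015", "1.020", "1.025")
    semiquant = tuple(str(i) for i in range(6))
    yn = ("yes", "no")
    return [
        ColumnMeta("age", NUMERIC),
        ColumnMeta("bp", NUMERIC),
        ColumnMeta("sg", NOMINAL, sg),
        ColumnMeta("al", NOMINAL, semiquant),
        ColumnMeta("su", NOMINAL, semiquant),
        ColumnMeta("rbc", NOMINAL, ("normal", "abnormal")),
        ColumnMeta("pc", NOMINAL, ("normal", "abnormal")),
        ColumnMeta("pcc", NOMINAL, ("present", "notpresent")),
        ColumnMeta("ba", NOMINAL, ("present", "notpresent")),
        ColumnMeta("bgr", NUMERIC),
        ColumnMeta("bu", NUMERIC),
        ColumnMeta("sc", NUMERIC),
        ColumnMeta("sod", NUMERIC),
        ColumnMeta("pot", NUMERIC),
        ColumnMeta("hemo", NUMERIC),
        ColumnMeta("pcv", NUMERIC),
        ColumnMeta("wbcc", NUMERIC),
        ColumnMeta("rbcc", NUMERIC),
        ColumnMeta("htn", NOMINAL, yn),
        ColumnMeta("dm", NOMINAL, yn),
        ColumnMeta("cad", NOMINAL, yn),
        ColumnMeta("appet", NOMINAL, ("good", "poor")),
        ColumnMeta("pe", NOMINAL, yn),
        ColumnMeta("ane", NOMINAL, yn),
    ]
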
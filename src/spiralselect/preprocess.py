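"""Leakage-safe preprocessing for mixed clinical tables.

Pipeline order: row filtering (records with at least half of their
attributes missing are dropped once, up front) → category domain
validation → Z-score outlier removal → SMOTE class balancing →
imputation + standardization + one-hot encoding.  Every statistic
(mode, median, mean, SD, valid category sets) is fitted on training rows
only and then applied unchanged to held-out rows, so no information from
an evaluation split can reach the fitted state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .dataset import NOMINAL, NUMERIC, ColumnMeta, TabularDataset


def _norm_cat(v) -> str:
    return str(v).strip().lower()


@dataclass
class PreprocessorState:
    """Training-fold statistics for imputation, validation and scaling.

    ``means``/``sds`` are computed on the median-imputed training column
    so that the transformed training fold is exactly zero-mean and
    unit-variance.
    """

    modes: dict[str, str] = field(default_factory=dict)
    medians: dict[str, float] = field(default_factory=dict)
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    valid_sets: dict[str, dict[str, str]] = field(default_factory=dict)
    fitted: bool = False

    def to_dict(self) -> dict:
        return {
            "modes": dict(self.modes),
            "medians": {k: float(v) for k, v in self.medians.items()},
            "means": {k: float(v) for k, v in self.means.items()},
            "sds": {k: float(v) for k, v in self.sds.items()},
            "valid_sets": {k: dict(v) for k, v in self.valid_sets.items()},
            "fitted": self.fitted,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessorState":
        return cls(
            modes=dict(d["modes"]), medians=dict(d["medians"]),
            means=dict(d["means"]), sds=dict(d["sds"]),
            valid_sets={k: dict(v) for k, v in d["valid_sets"].items()},
            fitted=bool(d["fitted"]),
        )


@dataclass(frozen=True)
class SmoteConfig:
    """Minority oversampling settings (k-NN interpolation)."""

    k_neighbors: int = 5
    target_ratio: float = 1.0  # minority:majority count after resampling
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not 0 < self.target_ratio <= 1:
            raise ValueError("target_ratio must lie in (0, 1]")


def fit_preprocessor(train: TabularDataset) -> PreprocessorState:
    """Fit modes (nominal), medians and scaling stats (numeric) on train.

    Mode ties break to the lexicographically smallest category.  A column
    with no observed training value is an error: there is nothing to
    impute from.
    """
    if train.n_samples == 0:
        raise ValueError("cannot fit a preprocessor on an empty dataset")
    st = PreprocessorState()
    for c in train.col_meta:
        col = train.X[c.name]
        obs = col.dropna()
        if obs.empty:
            raise ValueError(f"column {c.name!r} has no observed values")
        if c.kind == NOMINAL:
            counts = obs.astype(str).value_counts()
            top = counts[counts == counts.max()].index
            st.modes[c.name] = sorted(top)[0]
            st.valid_sets[c.name] = {_norm_cat(v): v for v in c.categories}
        else:
            vals = obs.to_numpy(dtype=float)
            med = float(np.median(vals))
            st.medians[c.name] = med
            imputed = col.to_numpy(dtype=float).copy()
            imputed[np.isnan(imputed)] = med
            st.means[c.name] = float(imputed.mean())
            st.sds[c.name] = float(imputed.std(ddof=0))
    st.fitted = True
    return st


def filter_high_missing_rows(ds: TabularDataset, threshold: float = 0.5
                             ) -> tuple[TabularDataset, int]:
    """Drop rows whose missing-attribute count is >= threshold * m.

    m counts the feature attributes only; the class label never counts.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    m = ds.n_features
    n_missing = ds.X.isna().sum(axis=1).to_numpy()
    keep = n_missing < threshold * m
    removed = int((~keep).sum())
    return ds.subset(np.flatnonzero(keep)), removed


def validate_categories(ds: TabularDataset, state: PreprocessorState
                        ) -> TabularDataset:
    """Map nominal cells onto their allowed category set.

    Case and surrounding whitespace are normalized; anything still
    outside the allowed set (``"unknown"``, misspellings, stray ``"?"``)
    becomes missing.  Numeric columns pass through untouched.
    """
    if not state.fitted:
        raise ValueError("preprocessor state is not fitted")
    out = ds.copy()
    for c in ds.col_meta:
        if c.kind != NOMINAL:
            continue
        lookup = state.valid_sets.get(c.name, {_norm_cat(v): v
                                               for v in c.categories})
        col = out.X[c.name].to_numpy(dtype=object)
        for i, v in enumerate(col):
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            col[i] = lookup.get(_norm_cat(v), np.nan)
        out.X[c.name] = col
    return out


def remove_numeric_outliers(ds: TabularDataset, state: PreprocessorState,
                            z_cut: float = 3.0) -> TabularDataset:
    """Drop rows with any observed numeric cell beyond ±z_cut training SDs.

    Constant training columns (sd = 0) contribute z = 0 everywhere.
    """
    if not state.fitted:
        raise ValueError("preprocessor state is not fitted")
    if z_cut <= 0:
        raise ValueError("z_cut must be positive")
    keep = np.ones(ds.n_samples, dtype=bool)
    for c in ds.col_meta:
        if c.kind != NUMERIC:
            continue
        sd = state.sds[c.name]
        if sd == 0:
            continue
        vals = ds.X[c.name].to_numpy(dtype=float)
        z = np.abs(vals - state.means[c.name]) / sd
        keep &= ~(z > z_cut) | np.isnan(vals)
    return ds.subset(np.flatnonzero(keep))


def transform(ds: TabularDataset, state: PreprocessorState) -> TabularDataset:
    """Impute, standardize and one-hot encode with fitted statistics.

    Missing nominals take the stored training mode; missing numerics the
    stored training median; numerics are scaled to training z-scores;
    nominal columns expand to one 0/1 column per allowed category.  The
    returned dataset is all-numeric and records, per encoded column, the
    index of the original feature it came from (``origin``), which lets a
    feature-selection mask over the original attributes pick encoded
    column groups.
    """
    if not state.fitted:
        raise ValueError("preprocessor state is not fitted")
    cols: dict[str, np.ndarray] = {}
    meta: list[ColumnMeta] = []
    origin: list[int] = []
    for j, c in enumerate(ds.col_meta):
        if c.kind == NUMERIC:
            vals = ds.X[c.name].to_numpy(dtype=float).copy()
            vals[np.isnan(vals)] = state.medians[c.name]
            sd = state.sds[c.name]
            vals = (vals - state.means[c.name]) / (sd if sd > 0 else 1.0)
            cols[c.name] = vals
            meta.append(ColumnMeta(c.name, NUMERIC))
            origin.append(j)
        else:
            raw = ds.X[c.name].to_numpy(dtype=object)
            filled = []
            allowed = set(c.categories)
            for v in raw:
                if v is None or (isinstance(v, float) and math.isnan(v)) \
                        or v not in allowed:
                    filled.append(state.modes[c.name])
                else:
                    filled.append(v)
            for cat in c.categories:
                name = f"{c.name}={cat}"
                cols[name] = np.array([1.0 if v == cat else 0.0
                                       for v in filled])
                meta.append(ColumnMeta(name, NUMERIC))
                origin.append(j)
    return TabularDataset(
        X=pd.DataFrame(cols), col_meta=meta, y=ds.y.copy(),
        informative_idx=ds.informative_idx, synthetic=ds.synthetic.copy(),
        origin=tuple(origin),
    )


def smote_oversample(train: TabularDataset, cfg: SmoteConfig
                     ) -> TabularDataset:
    """Append interpolated minority rows until the classes balance.

    Neighbours are found by Euclidean distance on the imputed,
    standardized, one-hot numeric encoding.  A synthetic row interpolates
    its parents' numeric cells, x_new = x_i + λ(x_j − x_i) with
    λ ~ U(0,1), and copies nominal cells from the nearer parent.
    Synthetic rows are flagged and must never enter evaluation splits.
    """
    counts = np.bincount(train.y, minlength=2)
    minority = int(np.argmin(counts))
    n_min, n_maj = counts[minority], counts[1 - minority]
    if n_min < cfg.k_neighbors + 1:
        raise ValueError(
            f"minority class has {n_min} rows; needs at least "
            f"{cfg.k_neighbors + 1} — use a smaller k_neighbors")
    n_target = int(round(cfg.target_ratio * n_maj))
    n_new = n_target - n_min
    if n_new <= 0:
        return train.copy()

    rng = np.random.default_rng(cfg.seed)
    state = fit_preprocessor(train)
    enc = transform(validate_categories(train, state), state)
    min_idx = np.flatnonzero(train.y == minority)
    E = enc.X.to_numpy(dtype=float)[min_idx]
    nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(E)
    _, neigh = nn.kneighbors(E)  # column 0 is the point itself

    num_cols = train.numeric_columns()
    raw_imputed = train.X.copy()
    for c in num_cols:
        vals = raw_imputed[c].to_numpy(dtype=float).copy()
        vals[np.isnan(vals)] = state.medians[c]
        raw_imputed[c] = vals
    for c in train.nominal_columns():
        raw_imputed[c] = raw_imputed[c].where(raw_imputed[c].notna(),
                                              state.modes[c])

    new_rows = []
    for _ in range(n_new):
        pos_i = int(rng.integers(n_min))
        pos_j = int(neigh[pos_i][1 + rng.integers(cfg.k_neighbors)])
        lam = float(rng.random())
        ri = raw_imputed.iloc[min_idx[pos_i]]
        rj = raw_imputed.iloc[min_idx[pos_j]]
        row = {}
        for c in train.col_meta:
            if c.kind == NUMERIC:
                xi, xj = float(ri[c.name]), float(rj[c.name])
                row[c.name] = xi + lam * (xj - xi)
            else:
                row[c.name] = ri[c.name] if lam <= 0.5 else rj[c.name]
        new_rows.append(row)

    X_new = pd.concat([train.X, pd.DataFrame(new_rows)], ignore_index=True)
    return TabularDataset(
        X=X_new, col_meta=list(train.col_meta),
        y=np.concatenate([train.y, np.full(n_new, minority, dtype=np.int8)]),
        informative_idx=train.informative_idx,
        synthetic=np.concatenate([train.synthetic,
                                  np.ones(n_new, dtype=bool)]),
        origin=train.origin,
    )


@dataclass(frozen=True)
class PreprocessConfig:
    """Per-fold preprocessing knobs."""

    z_cut: float = 3.0
    smote: SmoteConfig = SmoteConfig()
    apply_smote: bool = True


def preprocess_fold(train: TabularDataset, test: TabularDataset | None,
                    cfg: PreprocessConfig = PreprocessConfig()
                    ) -> tuple[TabularDataset, TabularDataset | None,
                               PreprocessorState]:
    """Run the per-fold chain and encode train (and optionally test).

    Validation and the Z-filter use statistics from the raw training
    fold; the scaling state is then refit on the cleaned training rows
    before SMOTE and encoding.  The held-out split is transformed with
    the training state only.
    """
    st0 = fit_preprocessor(train)
    tr = validate_categories(train, st0)
    tr = remove_numeric_outliers(tr, st0, cfg.z_cut)
    state = fit_preprocessor(tr)
    if cfg.apply_smote:
        tr = smote_oversample(tr, cfg.smote)
    tr_enc = transform(validate_categories(tr, state), state)
    te_enc = None
    if test is not None:
        te_enc = transform(validate_categories(test, state), state)
    return tr_enc, te_enc, state
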
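"""Synthetic CKD-like tabular data with a planted informative feature set.

The generator emulates the structure of the public screening table —
25 mixed-type attributes (11 numeric, 14 nominal with 2–5 levels), a
binary label with configurable prevalence, and missing-completely-at-
random entries — while planting a known subset of informative features
that drives the label through a logistic model.  That ground truth makes
feature-selection recovery and leakage tests possible without any
external download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import NOMINAL, NUMERIC, ColumnMeta, TabularDataset


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one simulated cohort.

    Defaults mirror the reference screening table: 400 records,
    11 numeric + 14 nominal attributes, 7 informative features, and a
    positive (CKD) prevalence of 250/400 = 0.625.  ``effect_size`` is the
    per-feature log-odds slope; ``noise_sd`` adds latent logit noise not
    explained by any recorded attribute.
    """

    n_samples: int = 400
    n_numeric: int = 11
    n_nominal: int = 14
    informative_idx: frozenset[int] = frozenset({0, 2, 5, 11, 14, 18, 22})
    class_ratio: float = 0.625
    missing_rate: float = 0.05
    effect_size: float = 4.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        m = self.n_numeric + self.n_nominal
        if self.n_samples < 1 or self.n_numeric < 0 or self.n_nominal < 0 or m == 0:
            raise ValueError("invalid dataset dimensions")
        if not all(0 <= j < m for j in self.informative_idx):
            raise ValueError("informative_idx outside feature range")
        if not 0.0 < self.class_ratio < 1.0:
            raise ValueError("class_ratio must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5)")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise ValueError("effect_size and noise_sd must be non-negative")

    @property
    def n_features(self) -> int:
        return self.n_numeric + self.n_nominal


def _solve_intercept(scores: np.ndarray, target: float) -> float:
    """Bisection for c with mean sigmoid(scores + c) == target."""
    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.mean(1.0 / (1.0 + np.exp(-(scores + mid)))) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_dataset(spec: SyntheticSpec) -> TabularDataset:
    """Draw one cohort under ``spec``.

    Numeric attributes are standard normal; nominal attributes take 2–5
    uniformly likely levels.  Each informative feature contributes a
    signed, unit-variance score to the label logit; the intercept is
    calibrated so the realised mean probability equals ``class_ratio``.
    Missingness is MCAR over feature cells at ``missing_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_features

    # interleave kinds deterministically: numerics first, then nominals,
    # shuffled once so informative indices span both types
    kinds = np.array([NUMERIC] * spec.n_numeric + [NOMINAL] * spec.n_nominal)
    rng.shuffle(kinds)

    col_meta: list[ColumnMeta] = []
    columns: dict[str, object] = {}
    scores = np.zeros((n, m))  # centred unit-variance score per feature
    n_num = n_nom = 0
    for j, kind in enumerate(kinds):
        if kind == NUMERIC:
            n_num += 1
            name = f"num{n_num:02d}"
            vals = rng.standard_normal(n)
            col_meta.append(ColumnMeta(name, NUMERIC))
            columns[name] = vals
            scores[:, j] = vals
        else:
            n_nom += 1
            name = f"nom{n_nom:02d}"
            n_levels = int(rng.integers(2, 6))
            levels = tuple(f"l{k}" for k in range(n_levels))
            codes = rng.integers(0, n_levels, size=n)
            col_meta.append(ColumnMeta(name, NOMINAL, levels))
            columns[name] = np.array([levels[c] for c in codes], dtype=object)
            # centred, unit-variance encoding of the level index
            sd = math.sqrt((n_levels**2 - 1) / 12.0)
            scores[:, j] = (codes - (n_levels - 1) / 2.0) / sd

    signs = rng.choice([-1.0, 1.0], size=m)
    inf = sorted(spec.informative_idx)
    logit = spec.effect_size * (scores[:, inf] * signs[inf]).sum(axis=1)
    logit = logit + spec.noise_sd * rng.standard_normal(n)
    logit = logit + _solve_intercept(logit, spec.class_ratio)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(np.int8)

    X = pd.DataFrame(columns)
    if spec.missing_rate > 0:
        mask = rng.random((n, m)) < spec.missing_rate
        for j, c in enumerate(col_meta):
            col = X[c.name].to_numpy(dtype=float if c.kind == NUMERIC else object)
            col[mask[:, j]] = np.nan
            X[c.name] = col

    return TabularDataset(
        X=X, col_meta=col_meta, y=y,
        informative_idx=frozenset(spec.informative_idx),
    )


def generating_logits(spec: SyntheticSpec) -> np.ndarray:
    """Recompute the label logits of ``generate_dataset`` (fixtures only).

    Used by tests to check that the label law depends only on the planted
    informative features.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_features
    kinds = np.array([NUMERIC] * spec.n_numeric + [NOMINAL] * spec.n_nominal)
    rng.shuffle(kinds)
    scores = np.zeros((n, m))
    for j, kind in enumerate(kinds):
        if kind == NUMERIC:
            scores[:, j] = rng.standard_normal(n)
        else:
            n_levels = int(rng.integers(2, 6))
            codes = rng.integers(0, n_levels, size=n)
            sd = math.sqrt((n_levels**2 - 1) / 12.0)
            scores[:, j] = (codes - (n_levels - 1) / 2.0) / sd
    signs = rng.choice([-1.0, 1.0], size=m)
    inf = sorted(spec.informative_idx)
    logit = spec.effect_size * (scores[:, inf] * signs[inf]).sum(axis=1)
    logit = logit + spec.noise_sd * rng.standard_normal(n)
    return logit + _solve_intercept(logit, spec.class_ratio)


def inject_high_missing_rows(ds: TabularDataset, k: int, frac_missing: float,
                             seed: int = 0) -> TabularDataset:
    """Force exactly k rows to carry ceil(frac_missing * m) missing cells.

    A fixture builder for the ≥50 %-missing row filter: with
    ``frac_missing`` above the filter threshold the injected rows — and,
    by construction, only they — are later removed.
    """
    if not 0 <= k <= ds.n_samples:
        raise ValueError(f"k={k} exceeds the {ds.n_samples} available rows")
    if not 0.0 < frac_missing <= 1.0:
        if k == 0:
            return ds.copy()
        raise ValueError("frac_missing must lie in (0, 1]")
    out = ds.copy()
    if k == 0:
        return out
    rng = np.random.default_rng(seed)
    m = ds.n_features
    target = math.ceil(frac_missing * m)
    rows = rng.choice(ds.n_samples, size=k, replace=False)
    miss = out.X.isna().to_numpy()
    for i in rows:
        have = int(miss[i].sum())
        if have > target:
            raise ValueError(
                f"row {i} already has {have} > {target} missing cells")
        observed = np.flatnonzero(~miss[i])
        add = rng.choice(observed, size=target - have, replace=False)
        for j in add:
            out.X.iat[i, int(j)] = np.nan
    return out
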
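"""End-to-end screening pipeline.

Workflow: one-time row filtering of the raw table → nested stratified
cross-validation, where each outer-training split is preprocessed,
feature-selected (spiral-search binary GSA against an inner-CV
surrogate), hyperparameter-tuned (elephant herding against inner-CV
MSE) and used to train the final deep belief network — then evaluated
on its untouched outer-test split → a deployment model fitted on the
full filtered table with exact Shapley attributions of the selected
biomarkers.

A single global seed fans out to per-stage seeds through a fixed
derivation, so a run is reproducible from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import TabularDataset
from .dbnn import DBNNClassifier, TrainConfig
from .eho import EHOConfig, HyperVector, mse_objective, run_eho
from .evaluate import CVPlan, EvaluationReport, nested_cv
from .explain import AttributionReport, explain_samples
from .preprocess import (PreprocessConfig, filter_high_missing_rows,
                         preprocess_fold)
from .selection import CVErrorEvaluator, FSConfig, run_sss_bgsa
from .synthetic import SyntheticSpec, generate_dataset


@dataclass(frozen=True)
class RunConfig:
    """Everything one experiment needs.

    Defaults follow the reference setup where a value is printed there:
    20 agents / 100 iterations / spiral radius 0.5 for selection; 5
    clans of 10, a = 0.5, β = 0.7 for tuning; 50 pretraining epochs,
    learning rate 0.01, momentum 0.9, dropout 0.3, L2 1e-4 for the
    network; 5 outer folds and 10 repeats for evaluation.
    """

    synthetic: SyntheticSpec = SyntheticSpec()
    preprocess: PreprocessConfig = PreprocessConfig()
    fs: FSConfig = FSConfig()
    train: TrainConfig = TrainConfig()
    eho: EHOConfig = EHOConfig()
    plan: CVPlan = CVPlan()
    layer_sizes: tuple[int, ...] = (64, 32)
    tune: bool = True
    # lighter training budget for the inner tuning objective; None means
    # use the full ``train`` settings for tuning evaluations as well
    tune_train: TrainConfig | None = None
    row_filter_threshold: float = 0.5
    threshold: float = 0.5
    explain_samples: int = 10
    seed: int = 0


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic fan-out of the global seed to per-stage seeds."""
    ss = np.random.SeedSequence(seed)
    names = ["synthetic", "preprocess", "selection", "tuning", "training",
             "evaluation", "explanation"]
    states = [int(c.generate_state(1)[0] % (2**31)) for c in
              ss.spawn(len(names))]
    return dict(zip(names, states))


def _with_seed(obj, seed: int):
    return dataclasses.replace(obj, seed=seed)


def fit_predict_fold(train: TabularDataset, test: TabularDataset,
                     cfg: RunConfig, seed: int
                     ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Fit the full modelling chain on one outer-training split.

    Returns (test CKD probabilities, selected mask over original
    features, fold details).  Nothing here reads the test rows except
    the final transform + prediction.
    """
    pp = dataclasses.replace(
        cfg.preprocess, smote=_with_seed(cfg.preprocess.smote, seed))
    tr_enc, te_enc, _state = preprocess_fold(train, test, pp)
    X = tr_enc.X.to_numpy(dtype=float)
    y = tr_enc.y
    origin = np.asarray(tr_enc.origin)

    evaluator = CVErrorEvaluator(X, y, tr_enc.origin,
                                 n_splits=cfg.plan.inner_folds, seed=seed)
    mask, f_best, trace = run_sss_bgsa(
        evaluator, train.n_features, _with_seed(cfg.fs, seed))
    cols = np.isin(origin, np.flatnonzero(mask))
    Xm = X[:, cols]

    if cfg.tune:
        tune_base = cfg.tune_train if cfg.tune_train is not None \
            else cfg.train

        def objective(pos):
            return mse_objective(Xm, y, HyperVector.from_position(pos),
                                 n_folds=cfg.plan.inner_folds,
                                 base_cfg=tune_base, seed=seed)

        incumbent = np.array([
            np.log10(cfg.train.learning_rate), cfg.train.momentum,
            np.log10(max(cfg.train.weight_decay, 1e-12)),
            float(cfg.layer_sizes[0]),
        ])
        best_pos, best_mse, _ = run_eho(objective,
                                        _with_seed(cfg.eho, seed + 1),
                                        incumbent=incumbent)
        hyper = HyperVector.from_position(best_pos)
        tcfg = dataclasses.replace(
            cfg.train, learning_rate=hyper.learning_rate,
            momentum=hyper.momentum, weight_decay=hyper.weight_decay,
            seed=seed)
        layers = hyper.layer_sizes
    else:
        hyper, best_mse = None, float("nan")
        tcfg = dataclasses.replace(cfg.train, seed=seed)
        layers = cfg.layer_sizes

    clf = DBNNClassifier(layers, tcfg).fit(Xm, y)
    Xt = te_enc.X.to_numpy(dtype=float)[:, cols]
    p_hat = clf.predict_proba(Xt)[:, 1]
    details = {"fitness": f_best, "trace": trace, "hyper": hyper,
               "inner_mse": best_mse, "n_selected": int(mask.sum())}
    return p_hat, mask, details


def run_nested_evaluation(ds: TabularDataset, cfg: RunConfig
                          ) -> EvaluationReport:
    """Nested CV of the full chain on an already row-filtered table."""

    def fold_fn(train, test, seed):
        p_hat, mask, _ = fit_predict_fold(train, test, cfg, seed)
        return p_hat, mask

    return nested_cv(ds, cfg.plan, fold_fn, threshold=cfg.threshold)


def fit_deployment_model(ds: TabularDataset, cfg: RunConfig, seed: int):
    """Selection + tuning + final model on the whole filtered table.

    Used for the explanation stage; generalization claims come from the
    nested CV, never from this model.
    """
    pp = dataclasses.replace(
        cfg.preprocess, smote=_with_seed(cfg.preprocess.smote, seed))
    tr_enc, _, state = preprocess_fold(ds, None, pp)
    X = tr_enc.X.to_numpy(dtype=float)
    y = tr_enc.y
    origin = np.asarray(tr_enc.origin)
    evaluator = CVErrorEvaluator(X, y, tr_enc.origin,
                                 n_splits=cfg.plan.inner_folds, seed=seed)
    mask, _, trace = run_sss_bgsa(evaluator, ds.n_features,
                                  _with_seed(cfg.fs, seed))
    cols = np.isin(origin, np.flatnonzero(mask))
    Xm = X[:, cols]
    tcfg = dataclasses.replace(cfg.train, seed=seed)
    clf = DBNNClassifier(cfg.layer_sizes, tcfg).fit(Xm, y)
    # one attribution player per selected original attribute: the group
    # of its encoded columns inside Xm
    sub_origin = origin[cols]
    names, groups = [], []
    for j in np.flatnonzero(mask):
        names.append(ds.feature_names[j])
        groups.append(np.flatnonzero(sub_origin == j))
    return clf, mask, cols, Xm, names, groups, trace


def explain_model(clf: DBNNClassifier, Xm: np.ndarray, names: list[str],
                  groups: list[np.ndarray], n_samples: int,
                  seed: int) -> AttributionReport:
    """Exact Shapley attributions for a seeded sample of patients
    against the training background, one player per selected
    attribute."""
    rng = np.random.default_rng(seed)
    bg_idx = rng.choice(len(Xm), size=min(50, len(Xm)), replace=False)
    sample_idx = rng.choice(len(Xm), size=min(n_samples, len(Xm)),
                            replace=False)

    def model_fn(rows):
        return clf.predict_proba(rows)[:, 1]

    return explain_samples(model_fn, Xm[sample_idx], Xm[bg_idx], names,
                           groups)


def run_full_pipeline(cfg: RunConfig, out_dir,
                      data: TabularDataset | None = None) -> dict:
    """Full workflow; writes artifacts under ``out_dir``.

    If ``data`` is None a synthetic cohort is generated under
    ``cfg.synthetic`` (with the fanned-out stage seed).  Returns the
    manifest dictionary.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg.seed)

    if data is None:
        data = generate_dataset(_with_seed(cfg.synthetic,
                                           seeds["synthetic"]))
    filtered, removed = filter_high_missing_rows(data,
                                                 cfg.row_filter_threshold)

    report = run_nested_evaluation(filtered, dataclasses.replace(
        cfg, plan=_with_seed(cfg.plan, seeds["evaluation"])))
    agg = report.aggregate()
    report.per_fold.to_csv(out / "per_fold_metrics.csv", index=False)
    report.per_repeat.to_csv(out / "per_repeat_calibration.csv",
                             index=False)
    agg.to_csv(out / "report.csv")
    report.calibration_table().to_csv(out / "calibration_curve.csv",
                                      index=False)

    clf, mask, cols, Xm, names, groups, trace = fit_deployment_model(
        filtered, cfg, seeds["training"])
    pd.DataFrame({
        "feature": filtered.feature_names,
        "selected": mask.astype(int),
    }).to_csv(out / "selected_features.csv", index=False)
    pd.DataFrame({"iteration": np.arange(len(trace)),
                  "best_fitness": trace}).to_csv(
        out / "convergence_trace.csv", index=False)

    attribution = explain_model(clf, Xm, names, groups,
                                cfg.explain_samples, seeds["explanation"])
    attribution.mean_abs.rename("mean_abs_shapley").to_csv(
        out / "global_importance.csv")
    attribution.phi.to_csv(out / "per_sample_shapley.csv", index=False)

    cfg_text = str(cfg)
    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "n_input_rows": int(data.n_samples),
        "rows_removed_by_filter": int(removed),
        "n_rows_after_filter": int(filtered.n_samples),
        "n_selected_features": int(mask.sum()),
        "selected_features": [n for n, m in
                              zip(filtered.feature_names, mask) if m],
        "metrics_mean": {k: float(v) for k, v in agg["mean"].items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump({"config": cfg_text, "seed": cfg.seed}, fh)
    return manifest
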
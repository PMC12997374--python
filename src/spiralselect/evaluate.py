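"""Nested stratified cross-validation and screening metrics.

The outer stratified k-fold loop (optionally repeated) measures
generalization only; every fitted quantity — imputation statistics,
oversampling, the feature mask, hyperparameters, the network itself —
is derived strictly from the outer-training split, with model selection
confined to inner folds of that split.  Metrics cover the confusion
table, ROC/AUC, and probability calibration (Brier score, expected
calibration error, calibration slope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class CVPlan:
    """Outer/inner fold counts and repeats (defaults 5 outer, 3 inner,
    10 repeats)."""

    outer_folds: int = 5
    inner_folds: int = 3
    repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("fold counts must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class PredictionSet:
    """Predicted CKD probabilities with truth and fold provenance."""

    y_true: np.ndarray
    p_hat: np.ndarray
    fold: np.ndarray | None = None
    repeat: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y_true = np.asarray(self.y_true, dtype=int)
        self.p_hat = np.asarray(self.p_hat, dtype=float)
        if self.y_true.shape != self.p_hat.shape:
            raise ValueError("y_true and p_hat must have equal length")
        if ((self.p_hat < 0) | (self.p_hat > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """The standard screening metrics from a 2x2 table.

    Ratios with a zero denominator are reported as NaN (missing), never
    coerced to zero.
    """
    if min(tp, fp, fn, tn) < 0 or tp + fp + fn + tn == 0:
        raise ValueError("counts must be non-negative with a positive total")

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else float("nan"))
    return {
        "accuracy": (tp + tn) / (tp + tn + fp + fn),
        "precision": precision,
        "sensitivity": recall,
        "specificity": ratio(tn, tn + fp),
        "f1": f1,
        "npv": ratio(tn, tn + fn),
        "fdr": ratio(fp, tp + fp),
        "fpr": ratio(fp, fp + tn),
        "fnr": ratio(fn, tp + fn),
    }


def confusion_from_predictions(pred: PredictionSet,
                               threshold: float = 0.5) -> dict[str, float]:
    y_hat = (pred.p_hat >= threshold).astype(int)
    tp = int(((pred.y_true == 1) & (y_hat == 1)).sum())
    fp = int(((pred.y_true == 0) & (y_hat == 1)).sum())
    fn = int(((pred.y_true == 1) & (y_hat == 0)).sum())
    tn = int(((pred.y_true == 0) & (y_hat == 0)).sum())
    return confusion_metrics(tp, fp, fn, tn)


def roc_auc(pred: PredictionSet) -> float:
    """Rank-based (Mann–Whitney) AUC with tie correction."""
    if np.unique(pred.y_true).size < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(pred.y_true, pred.p_hat))


def brier(pred: PredictionSet) -> float:
    """Mean squared difference between probability and outcome."""
    if pred.y_true.size == 0:
        raise ValueError("empty prediction set")
    return float(np.mean((pred.y_true - pred.p_hat) ** 2))


def ece(pred: PredictionSet, n_bins: int = 10,
        weighted: bool = False) -> float:
    """Expected calibration error over equal-width probability bins.

    The default averages |mean p − positive rate| over non-empty bins;
    ``weighted=True`` weights bins by their occupancy instead.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(pred.p_hat, edges[1:-1]), 0, n_bins - 1)
    gaps, weights = [], []
    for k in range(n_bins):
        in_bin = idx == k
        nk = int(in_bin.sum())
        if nk == 0:
            continue
        gaps.append(abs(pred.p_hat[in_bin].mean()
                        - pred.y_true[in_bin].mean()))
        weights.append(nk)
    gaps = np.asarray(gaps)
    if weighted:
        w = np.asarray(weights, dtype=float)
        return float((gaps * w).sum() / w.sum())
    return float(gaps.mean())


def calibration_curve_table(pred: PredictionSet,
                            n_bins: int = 10) -> pd.DataFrame:
    """Per-bin mean predicted probability and observed frequency."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(pred.p_hat, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for k in range(n_bins):
        in_bin = idx == k
        rows.append({
            "bin": k, "lower": edges[k], "upper": edges[k + 1],
            "n": int(in_bin.sum()),
            "mean_predicted": float(pred.p_hat[in_bin].mean())
            if in_bin.any() else float("nan"),
            "observed_rate": float(pred.y_true[in_bin].mean())
            if in_bin.any() else float("nan"),
        })
    return pd.DataFrame(rows)


def calibration_slope(pred: PredictionSet, clip: float = 1e-6) -> float:
    """Slope of the logistic recalibration of y on logit(p).

    1 means probabilities are on the right scale; < 1 overconfident,
    > 1 underconfident.  Returns NaN (with a warning) if the logistic
    fit fails to converge.
    """
    if np.unique(pred.y_true).size < 2:
        raise ValueError("calibration slope needs both classes present")
    p = np.clip(pred.p_hat, clip, 1 - clip)
    lp = np.log(p / (1 - p))
    import statsmodels.api as sm
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(pred.y_true, sm.add_constant(lp)).fit(disp=0)
        if not np.isfinite(fit.params).all():
            raise ValueError("non-finite fit")
        return float(fit.params[1])
    except Exception:  # perfect separation or non-convergence
        warnings.warn("calibration slope fit did not converge; "
                      "reporting missing", RuntimeWarning, stacklevel=2)
        return float("nan")


def paired_t_test(a, b) -> tuple[float, float]:
    """Two-sided paired t-test on the differences a - b.

    Degenerate inputs follow the documented contract: all-zero
    differences give (0, 1); zero-variance nonzero-mean differences give
    (±inf, 0) with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return 0.0, 1.0
        warnings.warn("zero-variance nonzero-mean differences",
                      RuntimeWarning, stacklevel=2)
        return float(np.sign(diff.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


@dataclass
class EvaluationReport:
    """Per-fold results with mean ± SD aggregation.

    ``per_fold`` holds one row per (repeat, outer fold) with the
    confusion metrics, AUC and Brier score; ``per_repeat`` holds pooled
    calibration measures (Brier, ECE, slope) per repeat;
    ``predictions`` the pooled outer-test prediction set.
    """

    per_fold: pd.DataFrame
    per_repeat: pd.DataFrame
    predictions: PredictionSet
    selected_masks: list[np.ndarray] = field(default_factory=list)
    ece_bins: int = 10

    def aggregate(self) -> pd.DataFrame:
        """Mean ± SD of every metric over all fold x repeat results."""
        num = self.per_fold.drop(columns=["repeat", "fold"])
        out = pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)})
        cal = self.per_repeat.drop(columns=["repeat"])
        cal_agg = pd.DataFrame({"mean": cal.mean(), "sd": cal.std(ddof=1)})
        cal_agg.index = ["pooled_" + str(i) for i in cal_agg.index]
        return pd.concat([out, cal_agg])

    def calibration_table(self) -> pd.DataFrame:
        return calibration_curve_table(self.predictions, self.ece_bins)


def evaluate_fold_predictions(y_true, p_hat, threshold: float = 0.5
                              ) -> dict[str, float]:
    pred = PredictionSet(y_true, p_hat)
    row = confusion_from_predictions(pred, threshold)
    row["auc"] = roc_auc(pred) if np.unique(pred.y_true).size == 2 \
        else float("nan")
    row["brier"] = brier(pred)
    return row


def nested_cv(ds, plan: CVPlan, fit_predict, threshold: float = 0.5,
              ece_bins: int = 10) -> EvaluationReport:
    """Generic nested-CV driver.

    ``fit_predict(train_ds, test_ds, seed)`` must fit the entire
    modelling chain (preprocessing, feature selection, tuning, final
    model) on ``train_ds`` only and return (p_hat for test rows,
    selected mask or None).  Stratified outer folds preserve class
    proportions within one sample; rows flagged synthetic may never
    appear in a test split (they are created per fold, after splitting).
    """
    rows, masks = [], []
    repeat_rows = []
    all_y, all_p, all_fold, all_rep = [], [], [], []
    for rep in range(plan.repeats):
        seed = plan.seed + rep
        skf = StratifiedKFold(n_splits=plan.outer_folds, shuffle=True,
                              random_state=seed)
        rep_y, rep_p = [], []
        for fold, (tr, te) in enumerate(skf.split(np.zeros(ds.n_samples),
                                                  ds.y)):
            train, test = ds.subset(tr), ds.subset(te)
            if test.synthetic.any():
                raise RuntimeError("synthetic rows leaked into a test split")
            fold_seed = (seed * 1009 + fold) % (2**31)
            p_hat, mask = fit_predict(train, test, fold_seed)
            row = evaluate_fold_predictions(test.y, p_hat, threshold)
            row.update({"repeat": rep, "fold": fold})
            rows.append(row)
            if mask is not None:
                masks.append(np.asarray(mask))
            rep_y.append(test.y)
            rep_p.append(np.asarray(p_hat))
            all_fold.extend([fold] * len(te))
            all_rep.extend([rep] * len(te))
        ry = np.concatenate(rep_y)
        rp = np.concatenate(rep_p)
        pooled = PredictionSet(ry, rp)
        repeat_rows.append({
            "repeat": rep,
            "brier": brier(pooled),
            "ece": ece(pooled, ece_bins),
            "calibration_slope": calibration_slope(pooled),
        })
        all_y.append(ry)
        all_p.append(rp)
    predictions = PredictionSet(
        np.concatenate(all_y), np.concatenate(all_p),
        fold=np.asarray(all_fold), repeat=np.asarray(all_rep))
    return EvaluationReport(
        per_fold=pd.DataFrame(rows), per_repeat=pd.DataFrame(repeat_rows),
        predictions=predictions, selected_masks=masks, ece_bins=ece_bins)
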
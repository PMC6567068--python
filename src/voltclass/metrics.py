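"""Evaluation: macro-F1, one-vs-rest ROC-AUC, repeated-split summaries,
Wilcoxon model comparison and holdout prediction reports.

The headline protocol scores each classifier on repeated stratified
train/test splits (25 for the study scale, fewer for desk runs) and
aggregates per-split macro-F1 and micro/macro ROC-AUC as median and IQR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score as _sk_f1
from sklearn.metrics import roc_auc_score as _sk_auc

from .classical import DTWParams, OneNNDTW, ProjectionParams, fit_lda, fit_pca_svm
from .dataset import ScanDataset
from .splits import SplitPlan, stratified_split

log = logging.getLogger(__name__)

__all__ = [
    "macro_f1",
    "roc_auc",
    "roc_auc_bruteforce",
    "confusion",
    "EvalSummary",
    "repeated_eval",
    "compare_models",
    "HoldoutReport",
    "holdout_predict",
    "ALL_MODEL_KINDS",
]

#: the seven classifiers compared in the study
ALL_MODEL_KINDS = ("pca_svm", "lda", "1nn_dtw", "lstm", "fcn", "lstm_fcn", "alstm_fcn")


def _check_proba(prob: np.ndarray) -> np.ndarray:
    prob = np.asarray(prob, dtype=float)
    if prob.ndim != 2:
        raise ValueError("probability table must be 2-D (scans x classes)")
    if not np.allclose(prob.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    return prob


def macro_f1(y_true: np.ndarray, prob_table: np.ndarray, threshold: float = 0.5,
             n_classes: int | None = None) -> float:
    """Unweighted mean of per-class F1 from argmax predictions.

    ``threshold`` is retained for per-class binary reporting conventions but
    multiclass labels come from the argmax; classes never predicted (or never
    present) contribute F1 = 0.
    """
    prob = _check_proba(prob_table)
    y = np.asarray(y_true, dtype=int)
    K = n_classes or prob.shape[1]
    if y.size and (y.min() < 0 or y.max() >= K):
        raise ValueError("label outside the class set")
    y_pred = np.argmax(prob, axis=1)
    return float(
        _sk_f1(y, y_pred, labels=np.arange(K), average="macro", zero_division=0)
    )


def roc_auc(
    y_true: np.ndarray,
    prob_table: np.ndarray,
    average: str = "micro",
    n_classes: int | None = None,
) -> float | np.ndarray:
    """One-vs-rest ROC-AUC: ``micro`` (pooled), ``macro`` or ``per_class``.

    A class with no positives (or no negatives) in the test set has an
    undefined AUC; it is returned as NaN per-class and excluded from the
    macro average with a logged warning.
    """
    prob = _check_proba(prob_table)
    y = np.asarray(y_true, dtype=int)
    K = n_classes or prob.shape[1]
    onehot = np.zeros((y.size, K))
    onehot[np.arange(y.size), y] = 1.0
    if average == "micro":
        return float(_sk_auc(onehot.ravel(), prob.ravel()))
    per_class = np.full(K, np.nan)
    for k in range(K):
        pos = onehot[:, k]
        if 0 < pos.sum() < y.size:
            per_class[k] = _sk_auc(pos, prob[:, k])
    if average == "per_class":
        return per_class
    if average == "macro":
        bad = np.flatnonzero(np.isnan(per_class))
        if bad.size:
            log.warning("classes %s have undefined AUC; excluded from macro", bad.tolist())
        return float(np.nanmean(per_class))
    raise ValueError(f"unknown average {average!r}")


def roc_auc_bruteforce(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Binary AUC as the pairwise-comparison probability (ties count 1/2).

    Independent reference for the trapezoidal ROC integration; quadratic in
    the number of scans.
    """
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need at least one positive and one negative")
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return float(wins / (pos.size * neg.size))


def confusion(y_true: np.ndarray, prob_table: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    """Confusion matrix at argmax; rows = true class, columns = predicted."""
    prob = _check_proba(prob_table)
    K = n_classes or prob.shape[1]
    return _sk_confusion(
        np.asarray(y_true, dtype=int), np.argmax(prob, axis=1), labels=np.arange(K)
    )


# -- model registry --------------------------------------------------------

def fit_predict_proba(
    kind: str,
    train_ds: ScanDataset,
    test_ds: ScanDataset,
    seed: int = 0,
    deep_cfg=None,
    lstm_cfg=None,
):
    """Fit one of the seven classifier kinds; return (model, test probabilities)."""
    from .nn.training import TrainConfig, desk_config, fit_deep

    if kind == "pca_svm":
        model = fit_pca_svm(train_ds, ProjectionParams(), seed=seed)
    elif kind == "lda":
        model = fit_lda(train_ds, ProjectionParams())
    elif kind == "1nn_dtw":
        model = OneNNDTW(DTWParams()).fit(train_ds)
    elif kind in ("lstm", "fcn", "lstm_fcn", "alstm_fcn"):
        cfg = deep_cfg or desk_config()
        cfg = replace(cfg, seed=seed)
        model = fit_deep(kind, train_ds, test_ds, cfg, lstm_cfg=lstm_cfg)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    return model, model.predict_proba(test_ds)


# -- repeated evaluation ---------------------------------------------------

@dataclass
class EvalSummary:
    """Per-repeat metric table plus its median/IQR aggregation."""

    model: str
    scheme: str
    per_repeat: pd.DataFrame  # columns: repeat, macro_f1, micro_roc_auc, macro_roc_auc
    per_class_auc: pd.DataFrame  # one row per repeat, one column per class
    confusions: list[np.ndarray] = field(default_factory=list)
    failures: list[tuple[int, str]] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.failures

    def aggregate(self) -> pd.DataFrame:
        """Median and IQR of every per-repeat metric."""
        rows = []
        for col in ("macro_f1", "micro_roc_auc", "macro_roc_auc"):
            vals = self.per_repeat[col].to_numpy()
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            rows.append({"metric": col, "median": med, "iqr": q3 - q1})
        return pd.DataFrame(rows)

    def median(self, metric: str = "micro_roc_auc") -> float:
        return float(self.per_repeat[metric].median())


def repeated_eval(
    model_kind: str,
    ds: ScanDataset,
    plan: SplitPlan | None = None,
    deep_cfg=None,
    lstm_cfg=None,
) -> EvalSummary:
    """Split / fit / score ``plan.n_repeats`` times and aggregate.

    Each repeat is seeded from the plan so any single repeat reproduces in
    isolation.  Failures (e.g. training divergence) are recorded and flagged
    rather than aborting the study.
    """
    plan = plan or SplitPlan.for_scheme(ds.scheme)
    K = len(ds.class_names)
    rows, auc_rows, confusions, failures = [], [], [], []
    for rep in range(plan.n_repeats):
        try:
            tr, te = stratified_split(ds, plan, rep)
            _, proba = fit_predict_proba(
                model_kind, tr, te, seed=plan.repeat_seed(rep), deep_cfg=deep_cfg,
                lstm_cfg=lstm_cfg,
            )
            y = te.y_indices()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # tiny splits: undefined per-class AUC
                rows.append(
                    {
                        "repeat": rep,
                        "macro_f1": macro_f1(y, proba, n_classes=K),
                        "micro_roc_auc": roc_auc(y, proba, "micro", n_classes=K),
                        "macro_roc_auc": roc_auc(y, proba, "macro", n_classes=K),
                    }
                )
                auc_rows.append(
                    dict(zip(ds.class_names, roc_auc(y, proba, "per_class", n_classes=K)))
                )
            confusions.append(confusion(y, proba, n_classes=K))
        except Exception as exc:  # noqa: BLE001 - survey must survive one bad repeat
            log.warning("repeat %d of %s failed: %s", rep, model_kind, exc)
            failures.append((rep, str(exc)))
    return EvalSummary(
        model=model_kind,
        scheme=ds.scheme,
        per_repeat=pd.DataFrame(rows),
        per_class_auc=pd.DataFrame(auc_rows),
        confusions=confusions,
        failures=failures,
    )


def compare_models(scores_a, scores_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired per-split scores.

    All-zero differences (identical score vectors) return p = 1 by
    convention.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired score vectors must have equal length")
    if np.allclose(a, b):
        log.info("identical paired scores; Wilcoxon p = 1 by convention")
        return 1.0
    return float(wilcoxon(a, b, alternative="two-sided").pvalue)


# -- holdout ---------------------------------------------------------------

@dataclass
class HoldoutReport:
    """Per-scan probabilities and correctness tally on a holdout set."""

    table: pd.DataFrame  # sample_id, true, predicted, correct, p_top, p_second + per-class columns
    n_correct: int
    n_total: int
    max_second_choice: float


def holdout_predict(model, holdout: ScanDataset) -> HoldoutReport:
    """Score a trained classifier on held-out scans.

    Reports the full probability vector per scan, the correct-count tally
    and the largest second-choice probability (a confidence summary).
    """
    if holdout.class_names != list(model.class_names):
        raise ValueError("holdout class scheme does not match the model")
    proba = model.predict_proba(holdout)
    order = np.argsort(proba, axis=1)
    pred_idx = order[:, -1]
    second = proba[np.arange(len(holdout)), order[:, -2]]
    names = list(model.class_names)
    pred = [names[i] for i in pred_idx]
    correct = [p == t for p, t in zip(pred, holdout.labels)]
    table = pd.DataFrame(
        {
            "sample_id": holdout.sample_ids,
            "true": holdout.labels,
            "predicted": pred,
            "correct": correct,
            "p_top": proba[np.arange(len(holdout)), pred_idx],
            "p_second": second,
        }
    )
    for k, c in enumerate(names):
        table[f"p_{c}"] = proba[:, k]
    return HoldoutReport(
        table=table,
        n_correct=int(sum(correct)),
        n_total=len(holdout),
        max_second_choice=float(second.max()) if len(holdout) else 0.0,
    )
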
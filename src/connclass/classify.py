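"""Nested leave-one-out classification of connectivity patterns.

Pipeline per fold: rank edges by two-sample t-test p-value on the training
subjects only, keep the ``n_features`` most discriminating, optionally
z-score with training-fold statistics, embed the training subjects with
locally linear embedding and project the left-out subject via the
out-of-sample extension, then classify with a Gaussian-RBF soft-margin SVM
(kernel exp(-||x-x'||^2 / (2 sigma^2))).  Patients are the positive class
throughout.  Performance is summarized by sensitivity SS = TP/(TP+FN),
specificity SC = TN/(TN+FP) and generalization rate GR = (TP+TN)/N, plus a
ROC curve swept over the per-subject decision scores.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml
from sklearn import metrics as skmetrics
from sklearn.svm import SVC

from .connectome import Cohort
from .group_stats import two_sample_t
from .lle import fit_lle, transform_lle

logger = logging.getLogger(__name__)

KERNEL_DIALECTS = ("2sigma2", "sigma2")


@dataclass
class PipelineConfig:
    """Classification pipeline parameters.

    Defaults follow the reference analysis: 50 selected features with an
    advisory p ceiling of 0.001, LLE with k = 23 neighbors and d = 15
    dimensions, RBF kernel width sigma = 3.  The SVM cost C is a
    conventional default (1.0).  ``kernel_dialect`` selects between
    exp(-r^2/(2 sigma^2)) (default) and exp(-r^2/sigma^2).
    """

    n_features: int = 50
    p_ceiling: float | None = 0.001
    k_lle: int = 23
    d_lle: int = 15
    sigma: float = 3.0
    C: float = 1.0
    use_lle: bool = True
    standardize: bool = True
    equal_var: bool = True
    kernel_dialect: str = "2sigma2"
    reg_lle: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.kernel_dialect not in KERNEL_DIALECTS:
            raise ValueError(f"kernel_dialect must be one of {KERNEL_DIALECTS}")

    @property
    def gamma(self) -> float:
        if self.kernel_dialect == "2sigma2":
            return 1.0 / (2.0 * self.sigma**2)
        return 1.0 / self.sigma**2

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)


@dataclass
class FoldResult:
    """Outcome of one leave-one-out fold."""

    subject_id: str
    true_label: int
    selected: np.ndarray  # sorted feature positions
    p_selected: np.ndarray  # p-values aligned with `selected`
    prediction: int
    score: float  # signed decision value, positive => patient


@dataclass
class CVResult:
    """Aggregate leave-one-out cross-validation outcome."""

    folds: list[FoldResult]
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float  # percent
    specificity: float  # percent
    generalization_rate: float  # percent
    scores: np.ndarray
    y_true: np.ndarray
    roc_sensitivity: np.ndarray
    roc_specificity: np.ndarray
    roc_thresholds: np.ndarray
    auc: float
    config: PipelineConfig

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "config": self.config.to_dict(),
            "confusion": {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn},
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "generalization_rate_pct": self.generalization_rate,
            "auc": self.auc,
            "scores": self.scores.tolist(),
            "y_true": self.y_true.tolist(),
            "roc": {
                "sensitivity": self.roc_sensitivity.tolist(),
                "specificity": self.roc_specificity.tolist(),
                "thresholds": self.roc_thresholds.tolist(),
            },
            "folds": [
                {
                    "subject_id": f.subject_id,
                    "true_label": int(f.true_label),
                    "selected": [int(s) for s in f.selected],
                    "p_selected": [float(p) for p in f.p_selected],
                    "prediction": int(f.prediction),
                    "score": float(f.score),
                }
                for f in self.folds
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Sensitivity, specificity, generalization rate — as percentages."""
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be present")
    ss = 100.0 * tp / (tp + fn)
    sc = 100.0 * tn / (tn + fp)
    gr = 100.0 * (tp + tn) / (tp + tn + fp + fn)
    return ss, sc, gr


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    n_features: int,
    equal_var: bool = True,
    p_ceiling: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rank features by two-sample t-test and keep the n_features smallest p.

    Ties in p are broken by larger |t|, then by smaller feature index.
    Features with zero variance in both groups receive p = 1.  Returns the
    selected positions sorted ascending and the full per-feature p-value
    vector.  If any selected p exceeds ``p_ceiling`` a warning is issued
    (selection is not altered).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.size}")
    if n_features > X.shape[1]:
        raise ValueError(
            f"n_features={n_features} exceeds feature length {X.shape[1]}"
        )
    t, p = two_sample_t(X[y == classes.max()], X[y == classes.min()],
                        equal_var=equal_var)
    abs_t = np.where(np.isfinite(t), np.abs(t), np.finfo(float).max)
    order = np.lexsort((np.arange(p.size), -abs_t, p))
    selected = np.sort(order[:n_features])
    if p_ceiling is not None and np.any(p[selected] > p_ceiling):
        worst = float(p[selected].max())
        warnings.warn(
            f"selected feature p-value {worst:.3g} exceeds ceiling {p_ceiling:g}",
            stacklevel=2,
        )
    return selected, p


def train_svm(
    Z: np.ndarray,
    y: np.ndarray,
    sigma: float,
    C: float = 1.0,
    kernel_dialect: str = "2sigma2",
    tol: float = 1e-7,
) -> SVC:
    """Fit a Gaussian-RBF soft-margin SVM; patient (label 1) is positive.

    The kernel is exp(-||x-x'||^2 / (2 sigma^2)) by default
    (gamma = 1/(2 sigma^2)); the ``sigma2`` dialect uses gamma = 1/sigma^2.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("need at least one sample per class")
    if np.allclose(Z, Z[0]):
        raise ValueError("degenerate training set: all points identical")
    gamma = 1.0 / (2.0 * sigma**2) if kernel_dialect == "2sigma2" else 1.0 / sigma**2
    model = SVC(kernel="rbf", gamma=gamma, C=C, tol=tol)
    model.fit(Z, y)
    return model


def roc_curve_points(
    scores: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """ROC swept over observed decision scores; AUC by the trapezoid rule.

    Returns (sensitivity, specificity, thresholds, auc); tied scores cross
    the threshold simultaneously.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("ROC requires scores from both classes")
    fpr, tpr, thresholds = skmetrics.roc_curve(y, scores)
    auc = float(skmetrics.auc(fpr, tpr))
    return tpr, 1.0 - fpr, thresholds, auc


def _fold_indices(n: int) -> list[tuple[np.ndarray, int]]:
    all_idx = np.arange(n)
    return [(np.delete(all_idx, i), i) for i in range(n)]


def run_loocv(cohort: Cohort, config: PipelineConfig | None = None) -> CVResult:
    """Nested leave-one-out cross-validation over a labeled cohort.

    Feature selection, standardization statistics, the embedding and the
    SVM are all fit on the N-1 training subjects of each fold; the held-out
    subject only ever passes through fitted transforms, so no test
    information can leak into model fitting.  The neighbor count and
    embedding dimension are clipped to what the fold's training size
    admits (k <= n_train - 1, d <= n_train - 2).
    """
    config = config or PipelineConfig()
    n = len(cohort)
    if n < 4:
        raise ValueError("LOOCV needs at least 4 subjects")
    X = cohort.feature_matrix()
    y = cohort.y
    if np.unique(y).size != 2:
        raise ValueError("cohort must contain both groups")
    if config.n_features > X.shape[1]:
        raise ValueError(
            f"n_features={config.n_features} exceeds feature length {X.shape[1]}"
        )
    logger.info(
        "LOOCV: N=%d (patients=%d, controls=%d), n_features=%d, "
        "k=%d, d=%d, sigma=%g, C=%g, use_lle=%s",
        n, cohort.n_patients, cohort.n_controls, config.n_features,
        config.k_lle, config.d_lle, config.sigma, config.C, config.use_lle,
    )
    folds: list[FoldResult] = []
    for train_idx, test_idx in _fold_indices(n):
        ytr = y[train_idx]
        if np.unique(ytr).size < 2:
            raise ValueError(
                f"fold leaving out subject {cohort.subject_ids[test_idx]} "
                "has a single-class training set"
            )
        sel, pvals = select_features(
            X[train_idx], ytr, config.n_features,
            equal_var=config.equal_var, p_ceiling=config.p_ceiling,
        )
        Xtr = X[train_idx][:, sel]
        xte = X[test_idx, sel]
        if config.standardize:
            mu = Xtr.mean(axis=0)
            sd = Xtr.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            Xtr = (Xtr - mu) / sd
            xte = (xte - mu) / sd
        if config.use_lle:
            n_tr = len(train_idx)
            k = min(config.k_lle, n_tr - 1)
            d = min(config.d_lle, n_tr - 2)
            model = fit_lle(Xtr, k=k, d=d, reg=config.reg_lle)
            Ztr = model.embedding
            zte = transform_lle(model, xte)
        else:
            Ztr, zte = Xtr, xte
        svm = train_svm(
            Ztr, ytr, sigma=config.sigma, C=config.C,
            kernel_dialect=config.kernel_dialect,
        )
        score = float(svm.decision_function(zte[None, :])[0])
        pred = int(score > 0)
        folds.append(
            FoldResult(
                subject_id=cohort.subject_ids[test_idx],
                true_label=int(y[test_idx]),
                selected=sel,
                p_selected=pvals[sel],
                prediction=pred,
                score=score,
            )
        )
    y_true = np.array([f.true_label for f in folds])
    y_pred = np.array([f.prediction for f in folds])
    scores = np.array([f.score for f in folds])
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    ss, sc, gr = compute_metrics(tp, tn, fp, fn)
    sens, spec, thresholds, auc = roc_curve_points(scores, y_true)
    return CVResult(
        folds=folds, tp=tp, tn=tn, fp=fp, fn=fn,
        sensitivity=ss, specificity=sc, generalization_rate=gr,
        scores=scores, y_true=y_true,
        roc_sensitivity=sens, roc_specificity=spec, roc_thresholds=thresholds,
        auc=auc, config=config,
    )
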
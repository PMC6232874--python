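"""QDA, polynomial-kernel SVM, and decision-tree classification with the
confusion-based report (Acc, Se, Sp, PPV, NPV).

Patients (MCI or AD) are the positive class throughout.  Features are
z-scored with statistics estimated on the training set only (inside the
fitted pipeline), so evaluation on held-out subjects is leakage-free.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierSpec",
    "ClassifierReport",
    "fit",
    "evaluate",
    "reconstruct_confusion",
    "MODELS",
]

MODELS = ("qda", "svm_poly", "dtree")


@dataclass(frozen=True)
class ClassifierSpec:
    """Model choice plus hyperparameters and seed."""

    model: str
    svm_degree: int = 3
    svm_cost: float = 1.0
    svm_coef0: float = 1.0
    qda_reg: float = 1e-6  # shrinkage of each class covariance toward its scaled identity
    dtree_max_depth: int | None = None
    dtree_min_leaf: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")
        if self.svm_degree < 1 or self.svm_cost <= 0 or self.qda_reg < 0:
            raise ValueError("hyperparameters out of range")


@dataclass
class ClassifierReport:
    """Confusion counts plus the five diagnostic percentages.

    Undefined ratios (zero denominator) are reported as None, never as 0.
    """

    tp: int
    fn: int
    tn: int
    fp: int
    model: str | None = None
    positive_label: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "tn", "fp"):
            if getattr(self, name) < 0:
                raise ValueError("confusion counts must be nonnegative")

    @staticmethod
    def _pct(num: int, den: int) -> float | None:
        return 100.0 * num / den if den else None

    @property
    def accuracy(self) -> float | None:
        return self._pct(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> float | None:
        return self._pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._pct(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return self._pct(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._pct(self.tn, self.tn + self.fn)

    def to_dict(self) -> dict:
        rnd = lambda x: None if x is None else round(x, 2)  # noqa: E731
        return {
            "model": self.model,
            "positive_label": self.positive_label,
            "seed": self.seed,
            "TP": self.tp, "FN": self.fn, "TN": self.tn, "FP": self.fp,
            "Acc": rnd(self.accuracy),
            "Se": rnd(self.sensitivity),
            "Sp": rnd(self.specificity),
            "PPV": rnd(self.ppv),
            "NPV": rnd(self.npv),
        }


def _build_estimator(spec: ClassifierSpec):
    if spec.model == "qda":
        clf = QuadraticDiscriminantAnalysis(reg_param=spec.qda_reg)
    elif spec.model == "svm_poly":
        clf = SVC(
            kernel="poly",
            degree=spec.svm_degree,
            C=spec.svm_cost,
            coef0=spec.svm_coef0,
            gamma="scale",
            random_state=spec.seed,
        )
    else:
        clf = DecisionTreeClassifier(
            criterion="gini",
            max_depth=spec.dtree_max_depth,
            min_samples_leaf=spec.dtree_min_leaf,
            random_state=spec.seed,
        )
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _row_hashes(x) -> set[str]:
    return {
        hashlib.sha1(np.ascontiguousarray(row, dtype=np.float64).tobytes()).hexdigest()
        for row in np.asarray(x, dtype=np.float64)
    }


def fit(spec: ClassifierSpec, train: FeatureTable):
    """Fit the model on a training table (standardization fitted inside)."""
    labels, counts = np.unique(train.y, return_counts=True)
    if labels.size < 2:
        raise ValueError("single-class training set")
    if np.any(counts < 2):
        raise ValueError("need at least two samples per class")
    est = _build_estimator(spec)
    with warnings.catch_warnings():
        # collinear selected features are expected with few subjects
        warnings.simplefilter("ignore", UserWarning)
        try:
            est.fit(train.x.to_numpy(), train.y)
        except np.linalg.LinAlgError as exc:
            # QDA on a rank-deficient class covariance: light shrinkage is not
            # enough for exactly singular data, so escalate to strong
            # shrinkage; with shrinkage disabled this is an error.
            if spec.model != "qda" or spec.qda_reg == 0:
                raise ValueError(
                    "singular class covariance; set qda_reg > 0 (covariance "
                    "shrinkage) or remove collinear features"
                ) from exc
            logger.warning(
                "QDA covariance singular at reg_param=%g; refitting with "
                "reg_param=0.5", spec.qda_reg,
            )
            est = _build_estimator(dataclasses.replace(spec, qda_reg=0.5))
            est.fit(train.x.to_numpy(), train.y)
    est._train_row_hashes = _row_hashes(train.x)  # for overlap detection
    est._spec = spec
    return est


def evaluate(model, test: FeatureTable, positive_label: str | None = None) -> ClassifierReport:
    """Confusion counts and diagnostic metrics on a held-out table."""
    if test.x.empty:
        raise ValueError("empty test set")
    positive = positive_label or test.positive_label
    hashes = getattr(model, "_train_row_hashes", set())
    if hashes & _row_hashes(test.x):
        logger.warning("evaluate: test rows overlap the training set")
    pred = model.predict(test.x.to_numpy())
    actual_pos = np.asarray(test.y) == positive
    pred_pos = np.asarray(pred) == positive
    spec = getattr(model, "_spec", None)
    return ClassifierReport(
        tp=int(np.sum(actual_pos & pred_pos)),
        fn=int(np.sum(actual_pos & ~pred_pos)),
        tn=int(np.sum(~actual_pos & ~pred_pos)),
        fp=int(np.sum(~actual_pos & pred_pos)),
        model=spec.model if spec else None,
        positive_label=str(positive),
        seed=spec.seed if spec else None,
    )


def reconstruct_confusion(
    se_pct: float, sp_pct: float, n_pos: int, n_neg: int
) -> ClassifierReport:
    """Integer confusion matrix implied by rounded sensitivity/specificity.

    Rounds Se * n_pos / 100 and Sp * n_neg / 100 to the nearest integers;
    given the group sizes this pins down TP/FN/TN/FP exactly, from which the
    remaining metrics (Acc, PPV, NPV) follow.
    """
    tp = int(round(se_pct * n_pos / 100.0))
    tn = int(round(sp_pct * n_neg / 100.0))
    return ClassifierReport(tp=tp, fn=n_pos - tp, tn=tn, fp=n_neg - tn)
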
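"""Two-phase motor-imagery classification and evaluation metrics.

Phase 1 is a small multilayer perceptron producing class
probabilities.  Phase 2 is an adaptive RBF-kernel SVM trained on the
original features concatenated with the *out-of-fold* phase-1
probabilities (so phase 2 never sees optimistic in-sample
probabilities), with per-sample weights that up-weight designated
new-session trials by ``adaptation_rate`` — a simple, auditable way of
adapting to session-to-session non-stationarity.  Evaluation reports
accuracy, Cohen's kappa, per-class and macro precision/recall/F1,
misclassification rate (= 1 - accuracy) and the confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

__all__ = ["TwoPhaseClassifier", "EvalReport", "evaluate", "make_phase1"]


def make_phase1(hidden: int = 64, seed: int | None = 0, max_iter: int = 500) -> MLPClassifier:
    """Phase-1 MLP: one hidden layer, early stopping on a 20% split."""
    return MLPClassifier(
        hidden_layer_sizes=(hidden,),
        early_stopping=True,
        validation_fraction=0.2,
        n_iter_no_change=25,  # small EEG feature sets plateau slowly
        max_iter=max_iter,
        random_state=seed,
    )


class TwoPhaseClassifier(BaseEstimator, ClassifierMixin):
    """ANN phase 1 feeding an adaptive SVM phase 2.

    Parameters
    ----------
    hidden : int
        Phase-1 hidden-layer width.
    adaptation_rate : float
        Sample weight applied to trials marked as new-session in
        ``fit(..., new_session=mask)``; 1.0 disables adaptation.
    C_grid : tuple of float
        Phase-2 SVM regularisation grid, selected by stratified CV.
    cv : int
        Folds both for out-of-fold phase-1 probabilities and for the
        phase-2 grid.
    random_state : int
        Seeds the MLP, the fold shuffling, and nothing else.
    """

    def __init__(
        self,
        hidden: int = 64,
        adaptation_rate: float = 1.0,
        C_grid: tuple = (0.1, 1.0, 10.0),
        cv: int = 5,
        random_state: int = 0,
        max_iter: int = 500,
    ):
        self.hidden = hidden
        self.adaptation_rate = adaptation_rate
        self.C_grid = C_grid
        self.cv = cv
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, X, y, new_session: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        counts = np.min([np.sum(y == c) for c in self.classes_])
        if counts < 8:
            raise ValueError("need at least 8 samples per class")
        ann = make_phase1(self.hidden, self.random_state, self.max_iter)
        skf = StratifiedKFold(self.cv, shuffle=True, random_state=self.random_state)
        proba_oof = cross_val_predict(clone(ann), X, y, cv=skf, method="predict_proba")
        self.ann_ = clone(ann).fit(X, y)
        Z = np.hstack([X, proba_oof])
        weights = np.ones(len(y))
        if new_session is not None:
            weights[np.asarray(new_session, dtype=bool)] = self.adaptation_rate
        best_C, best_score = None, -np.inf
        for C in self.C_grid:
            scores = []
            for tr, te in skf.split(Z, y):
                svm = SVC(C=C, kernel="rbf", gamma="scale")
                svm.fit(Z[tr], y[tr], sample_weight=weights[tr])
                scores.append(svm.score(Z[te], y[te]))
            s = float(np.mean(scores))
            if s > best_score:
                best_C, best_score = C, s
        self.svm_ = SVC(C=best_C, kernel="rbf", gamma="scale")
        self.svm_.fit(Z, y, sample_weight=weights)
        self.best_C_ = best_C
        return self

    def _check_fitted(self):
        if not hasattr(self, "svm_"):
            raise ValueError("model is not fitted")

    def predict_phase1_proba(self, X) -> np.ndarray:
        self._check_fitted()
        return self.ann_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        Z = np.hstack([X, self.ann_.predict_proba(X)])
        return self.svm_.predict(Z)


@dataclass
class EvalReport:
    """Classification metrics on one labelled set."""

    accuracy: float
    kappa: float
    misclassification_rate: float
    precision: dict
    recall: dict
    f1: dict
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray
    classes: np.ndarray

    def summary(self) -> str:
        lines = [
            f"accuracy            {self.accuracy:.4f}",
            f"kappa               {self.kappa:.4f}",
            f"misclassification   {self.misclassification_rate:.4f}",
            f"macro precision     {self.macro_precision:.4f}",
            f"macro recall        {self.macro_recall:.4f}",
            f"macro F1            {self.macro_f1:.4f}",
            "confusion (rows = true):",
        ]
        for c, row in zip(self.classes, self.confusion):
            lines.append(f"  {c!s:>6} " + " ".join(f"{v:6d}" for v in row))
        return "\n".join(lines)


def evaluate(y_pred, y_true, labels=None) -> EvalReport:
    """Standard multiclass metrics; kappa = (p_o - p_e) / (1 - p_e).

    ``labels`` fixes the class set; predictions or truths outside it
    raise.
    """
    y_pred = np.asarray(y_pred)
    y_true = np.asarray(y_true)
    if y_pred.shape != y_true.shape or y_true.size == 0:
        raise ValueError("predictions and truths must be equal-length, non-empty")
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred]))
    else:
        labels = np.asarray(labels)
        seen = set(np.unique(np.concatenate([y_true, y_pred])).tolist())
        if not seen <= set(labels.tolist()):
            raise ValueError(f"labels outside class set: {sorted(seen - set(labels.tolist()))}")
    acc = metrics.accuracy_score(y_true, y_pred)
    kappa = metrics.cohen_kappa_score(y_true, y_pred, labels=labels)
    prec, rec, f1, _ = metrics.precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    conf = metrics.confusion_matrix(y_true, y_pred, labels=labels)
    return EvalReport(
        accuracy=float(acc),
        kappa=float(kappa),
        misclassification_rate=float(1.0 - acc),
        precision={str(c): float(v) for c, v in zip(labels, prec)},
        recall={str(c): float(v) for c, v in zip(labels, rec)},
        f1={str(c): float(v) for c, v in zip(labels, f1)},
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
        confusion=conf,
        classes=labels,
    )
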
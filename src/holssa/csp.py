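"""Common Spatial Patterns: spatial filters and log-variance features.

For two conditions with average (trace-normalised) covariances C1 and
C2, CSP finds filters w maximising the variance ratio, i.e. the
generalized eigenproblem C1 w = lambda (C1 + C2) w.  The filters here
are computed by whitening the pooled covariance and diagonalising the
whitened C1 (numerically robust, and independent of the dense
generalized eigensolver used as an oracle in the tests).  Features are
log-normalised variances of epochs projected on the first and last
``n_pairs`` filters.  Multiclass handling is one-vs-rest with
concatenated per-model features.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["CSP", "OneVsRestCSP", "fit_csp", "fit_csp_ovr", "extract_features"]

_EPS = 1e-30


def _class_covariances(epochs: np.ndarray, y: np.ndarray, reg: float):
    """Per-class averages of trace-normalised epoch covariances."""
    classes = np.unique(y)
    covs = {}
    n_ch = epochs.shape[1]
    for c in classes:
        acc = np.zeros((n_ch, n_ch))
        members = np.flatnonzero(y == c)
        for k in members:
            X = epochs[k] - epochs[k].mean(axis=1, keepdims=True)
            C = X @ X.T
            acc += C / max(np.trace(C), _EPS)
        covs[c] = acc / len(members)
    return classes, covs


class CSP(BaseEstimator, TransformerMixin):
    """Two-class CSP transformer.

    Fitted attributes
    -----------------
    filters_ : ndarray (n_channels, n_channels)
        Columns sorted by descending eigenvalue; satisfies
        ``filters_.T @ (C1 + C2) @ filters_ = I``.
    eigenvalues_ : ndarray
        Variance fractions of class ``classes_[0]``, descending;
        paired filters satisfy lambda_1 + lambda_2(mirror) = 1.
    """

    def __init__(self, n_pairs: int = 3, reg: float = 1e-8):
        self.n_pairs = n_pairs
        self.reg = reg

    def fit(self, epochs: np.ndarray, y: np.ndarray):
        epochs = np.asarray(epochs, dtype=float)
        y = np.asarray(y)
        if epochs.ndim != 3:
            raise ValueError("epochs must be trials x channels x samples")
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError(f"CSP needs exactly 2 classes, got {len(classes)}")
        if min(np.sum(y == c) for c in classes) < 2:
            raise ValueError("need at least 2 epochs per class")
        classes, covs = _class_covariances(epochs, y, self.reg)
        C1, C2 = covs[classes[0]], covs[classes[1]]
        pooled = C1 + C2
        n_ch = pooled.shape[0]
        w, V = np.linalg.eigh(pooled)
        if w.min() < self.reg * np.trace(pooled):
            warnings.warn("rank-deficient pooled covariance; applying ridge")
            pooled = pooled + self.reg * np.trace(pooled) * np.eye(n_ch)
            w, V = np.linalg.eigh(pooled)
        P = (V / np.sqrt(w)) @ V.T  # symmetric whitener of the pooled covariance
        lam, U = np.linalg.eigh(P @ C1 @ P)
        order = np.argsort(lam)[::-1]
        self.classes_ = classes
        self.eigenvalues_ = lam[order]
        self.filters_ = P @ U[:, order]
        return self

    def _selected(self) -> np.ndarray:
        n_ch = self.filters_.shape[1]
        k = min(self.n_pairs, n_ch // 2)
        idx = np.r_[np.arange(k), np.arange(n_ch - k, n_ch)]
        return self.filters_[:, idx]

    def transform(self, epochs: np.ndarray) -> np.ndarray:
        """Log-normalised variance features, one row per epoch."""
        epochs = np.asarray(epochs, dtype=float)
        if epochs.shape[-1] < 2:
            raise ValueError("epochs must have at least 2 samples")
        W = self._selected()
        feats = np.empty((epochs.shape[0], W.shape[1]))
        for k, ep in enumerate(epochs):
            proj = W.T @ (ep - ep.mean(axis=1, keepdims=True))
            v = proj.var(axis=1)
            feats[k] = np.log(np.maximum(v / max(v.sum(), _EPS), _EPS))
        return feats


class OneVsRestCSP(BaseEstimator, TransformerMixin):
    """One CSP model per class against the rest; features concatenated.

    Feature dimension is ``n_classes * 2 * n_pairs``.
    """

    def __init__(self, n_pairs: int = 3, reg: float = 1e-8):
        self.n_pairs = n_pairs
        self.reg = reg

    def fit(self, epochs: np.ndarray, y: np.ndarray):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        self.models_ = []
        for c in self.classes_:
            if np.sum(y == c) < 2:
                raise ValueError(f"class {c} has fewer than 2 epochs")
            model = CSP(self.n_pairs, self.reg)
            model.fit(np.asarray(epochs, dtype=float), (y == c).astype(int))
            self.models_.append(model)
        return self

    def transform(self, epochs: np.ndarray) -> np.ndarray:
        return np.hstack([m.transform(epochs) for m in self.models_])


def fit_csp(epochs, y, n_pairs: int = 3) -> CSP:
    return CSP(n_pairs=n_pairs).fit(epochs, y)


def fit_csp_ovr(epochs, y, n_pairs: int = 3) -> OneVsRestCSP:
    return OneVsRestCSP(n_pairs=n_pairs).fit(epochs, y)


def extract_features(epochs, model) -> np.ndarray:
    return model.transform(epochs)
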
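"""Online recursive ICA: streaming whitening and demixing updates.

Per sample, a running mean/covariance with forgetting factor ``l_r``
yields a sphering matrix (inverse square root of the covariance), and
the demixing inverse is updated by the multiplicative relative-gradient
rule

    S^{-1} <- S^{-1} + l_r * (I - f(y) y^T) S^{-1},    y = S^{-1} a,

with ``a`` the whitened sample and ``f`` an elementwise nonlinearity
(tanh for super-Gaussian sources such as EEG, cubic for sub-Gaussian).
``y`` is the current source estimate; at the separating solution
E[f(y) y^T] = I and the expected update vanishes.  The update is the
rank-1-structured form whose inverse-free propagation corresponds to a
Sherman-Morrison step on the mixing estimate ``S``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = ["DemixingState", "ORICA", "init_state", "whiten_update", "demix_update", "separate"]

_NONLINEARITIES = {
    "tanh": np.tanh,
    "cubic": lambda y: y**3,
}


@dataclass
class DemixingState:
    """Mutable state of the streaming separator."""

    S_inv: np.ndarray            # demixing inverse (r x r)
    whitener: np.ndarray         # sphering matrix (r x r)
    mean: np.ndarray             # running mean (r,)
    cov: np.ndarray              # running covariance (r x r)
    l_r: float
    nonlinearity: str
    n_seen: int = 0
    anneal: float | None = None  # l_r / n^anneal when set
    whiten_mode: str = "forget"  # 'forget': EWMA with factor l_r; 'average': converging

    @property
    def f(self):
        return _NONLINEARITIES[self.nonlinearity]

    def effective_lr(self) -> float:
        if self.anneal is None or self.n_seen == 0:
            return self.l_r
        return self.l_r / self.n_seen**self.anneal


def init_state(
    r: int,
    l_r: float = 0.005,
    nonlinearity: str = "tanh",
    seed: int | None = None,
    anneal: float | None = None,
    whiten_mode: str = "forget",
) -> DemixingState:
    """Identity-initialised state for ``r`` channels."""
    if r < 2:
        raise ValueError(f"need at least 2 channels, got {r}")
    if not 0 < l_r < 1:
        raise ValueError(f"learning rate must be in (0, 1), got {l_r}")
    if nonlinearity not in _NONLINEARITIES:
        raise ValueError(f"unknown nonlinearity {nonlinearity!r}")
    if whiten_mode not in ("forget", "average"):
        raise ValueError(f"unknown whiten_mode {whiten_mode!r}")
    return DemixingState(
        S_inv=np.eye(r),
        whitener=np.eye(r),
        mean=np.zeros(r),
        cov=np.eye(r),
        l_r=l_r,
        nonlinearity=nonlinearity,
        anneal=anneal,
        whiten_mode=whiten_mode,
    )


def _inv_sqrt(cov: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    w, V = np.linalg.eigh(cov)
    floor = eps * max(w.max(), eps)
    if w.min() < floor:
        logger.warning("near-singular running covariance; regularising")
        w = np.maximum(w, floor)
    return (V / np.sqrt(w)) @ V.T


def whiten_update(state: DemixingState, a: np.ndarray) -> np.ndarray:
    """Fold one raw sample into mean/covariance; return it whitened.

    In ``forget`` mode the rate is max(l_r, 1/(n+2)): plain running
    averages at first, then an EWMA with forgetting factor ``l_r`` that
    tracks nonstationary streams.  In ``average`` mode the rate stays
    1/(n+2), so the covariance converges to the record-wide estimate —
    the right choice when a fixed offline record is separated and the
    final whitener is applied to all of it.
    """
    a = np.asarray(a, dtype=float).ravel()
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite sample")
    eta = 1.0 / (state.n_seen + 2)
    if state.whiten_mode == "forget":
        eta = max(state.l_r, eta)
    state.mean = (1 - eta) * state.mean + eta * a
    d = a - state.mean
    state.cov = (1 - eta) * state.cov + eta * np.outer(d, d)
    state.whitener = _inv_sqrt(state.cov)
    return state.whitener @ d


def demix_update(
    state: DemixingState, a: np.ndarray, clip: float | None = 4.0
) -> DemixingState:
    """One multiplicative demixing step on the whitened sample ``a``.

    ``clip`` bounds the norm of the source estimate ``y`` used in the
    update at ``clip * sqrt(r)`` (whitened data has E||y||^2 = r), so a
    single outlier sample — an eye blink, say — cannot blow up the
    recursion; typical samples are unaffected and see exactly the
    multiplicative rule.  A step that would still leave ``S_inv``
    non-finite (or absurdly large) is rejected and the learning rate
    halved.
    """
    a = np.asarray(a, dtype=float).ravel()
    y = state.S_inv @ a
    if clip is not None:
        bound = clip * np.sqrt(len(y))
        norm = np.linalg.norm(y)
        if norm > bound:
            y = y * (bound / norm)
    lr = state.effective_lr()
    cand = state.S_inv + lr * (np.eye(len(y)) - np.outer(state.f(y), y)) @ state.S_inv
    if not np.all(np.isfinite(cand)) or np.abs(cand).max() > 1e12:
        warnings.warn("rejected divergent demixing update; halving learning rate")
        state.l_r /= 2
    else:
        state.S_inv = cand
    state.n_seen += 1
    return state


def _gaussianity_warning(X: np.ndarray) -> None:
    exk = stats.kurtosis(X, axis=1, fisher=True)
    if np.all(np.abs(exk) < 0.1):
        logger.warning(
            "all inputs look Gaussian (|excess kurtosis| < 0.1); "
            "ICA rotation is unidentifiable"
        )


def separate(
    X: np.ndarray,
    l_r: float = 0.005,
    nonlinearity: str = "tanh",
    n_passes: int = 3,
    anneal: float | None = None,
    seed: int | None = None,
    whiten_mode: str = "average",
    average_final_pass: bool = True,
) -> tuple[np.ndarray, np.ndarray, DemixingState]:
    """Run the streaming separator over ``X`` (channels x samples).

    Columns are streamed through the whitening and demixing updates
    (``n_passes`` sweeps for offline data); the components returned are
    one fixed demixing transform applied to the whole whitened record,
    and the mixing estimate is its pseudo-inverse, suitable for
    back-projection.  Because a single transform serves the entire
    record, the offline defaults favour convergence over tracking:
    ``average`` whitening, and a Polyak-style average of the demixing
    matrix over the final pass instead of its end-of-stream snapshot
    (the constant-rate recursion fluctuates around the separating
    solution; averaging cancels the fluctuations).  For truly
    streaming use pass ``whiten_mode='forget'`` and
    ``average_final_pass=False``.

    Returns (components r x n, mixing_est r x r, state).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (channels x samples)")
    r, n = X.shape
    if r < 2:
        raise ValueError("need at least 2 channels")
    if n < 10 * r:
        warnings.warn(f"only {n} samples for {r} channels; results may be poor")
    _gaussianity_warning(X)
    state = init_state(
        r, l_r, nonlinearity, seed=seed, anneal=anneal, whiten_mode=whiten_mode
    )
    S_inv_bar = np.zeros((r, r))
    for p in range(n_passes):
        final = p == n_passes - 1
        for t in range(n):
            aw = whiten_update(state, X[:, t])
            demix_update(state, aw)
            if final and average_final_pass:
                S_inv_bar += state.S_inv
    S_demix = S_inv_bar / n if average_final_pass else state.S_inv
    W_total = S_demix @ state.whitener
    components = W_total @ (X - state.mean[:, None])
    mixing_est = np.linalg.pinv(W_total)
    return components, mixing_est, state


class ORICA(BaseEstimator, TransformerMixin):
    """Scikit-learn wrapper: samples are rows, channels are columns.

    Fitted attributes: ``unmixing_`` (r x r, full transform including
    sphering), ``mixing_`` (its pseudo-inverse), ``mean_``, ``state_``.
    """

    def __init__(
        self,
        l_r: float = 0.005,
        nonlinearity: str = "tanh",
        n_passes: int = 3,
        anneal: float | None = None,
        whiten_mode: str = "average",
        average_final_pass: bool = True,
        random_state: int | None = None,
    ):
        self.l_r = l_r
        self.nonlinearity = nonlinearity
        self.n_passes = n_passes
        self.anneal = anneal
        self.whiten_mode = whiten_mode
        self.average_final_pass = average_final_pass
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        _, mixing, state = separate(
            X.T,
            l_r=self.l_r,
            nonlinearity=self.nonlinearity,
            n_passes=self.n_passes,
            anneal=self.anneal,
            seed=self.random_state,
            whiten_mode=self.whiten_mode,
            average_final_pass=self.average_final_pass,
        )
        self.state_ = state
        self.mixing_ = mixing
        self.unmixing_ = np.linalg.pinv(mixing)
        self.mean_ = state.mean
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return ((X - self.mean_) @ self.unmixing_.T)

    def inverse_transform(self, S):
        return np.asarray(S) @ self.mixing_.T + self.mean_
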
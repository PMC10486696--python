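"""Rule-based labelling of independent components and artifact removal.

Each component gets a spectral/statistical fingerprint (band-power
ratios from a Welch PSD, sample kurtosis, cardiac-band periodicity of
the smoothed energy envelope) and a transparent first-match decision
list assigns one label: line noise, muscle (EMG), eye (EOG), heart
(ECG), brain, or other.  Cleaning zeroes the non-kept components and
back-projects through the estimated mixing matrix.

The thresholds are explicit and configurable; this is a deliberately
auditable scorer, not a trained probabilistic classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

__all__ = [
    "ComponentScore",
    "LabelThresholds",
    "score_component",
    "label_component",
    "score_and_label",
    "remove_and_backproject",
]

LABELS = ("brain", "eye", "muscle", "heart", "line_noise", "other")


@dataclass(frozen=True)
class LabelThresholds:
    """First-match decision thresholds (all ratios in [0, 1])."""

    line: float = 0.5      # 49-51 Hz fraction
    emg: float = 0.5       # 20-60 Hz fraction
    eog: float = 0.4       # 1-4 Hz fraction, jointly with kurtosis
    kurtosis: float = 5.0  # Pearson kurtosis (normal = 3)
    heart: float = 0.3     # envelope autocorrelation peak in 0.6-1.5 s
    brain: float = 0.3     # 8-13 Hz fraction


@dataclass
class ComponentScore:
    """Spectral and statistical fingerprint of one component."""

    index: int
    kurtosis: float
    lowfreq_ratio: float   # 1-4 Hz / total
    midband_ratio: float   # 8-13 Hz / total
    highfreq_ratio: float  # 20-60 Hz / total
    line_ratio: float      # 49-51 Hz / total
    periodicity: float     # cardiac-band envelope autocorrelation peak
    period_s: float        # lag of that peak, seconds
    label: str = "other"


def _band_fraction(f: np.ndarray, p: np.ndarray, lo: float, hi: float) -> float:
    total = p.sum()
    if total <= 0:
        return 0.0
    m = (f >= lo) & (f <= hi)
    return float(p[m].sum() / total)


def _cardiac_periodicity(x: np.ndarray, fs: float) -> tuple[float, float]:
    """Prominence of an envelope-autocorrelation peak at cardiac lags.

    The score is the autocorrelation of the low-passed energy envelope
    at its best lag in 0.6-1.5 s *minus the minimum at shorter lags*
    (>= 0.25 s).  A quasi-periodic spike train dips between beats and
    peaks again at the inter-beat interval, giving a large prominence;
    a slowly drifting envelope (e.g. waxing-waning alpha) decays
    monotonically and scores near zero.
    """
    env = np.abs(x)
    # smooth below ~8 Hz so carrier-frequency structure cannot alias in
    sos = signal.butter(4, min(8.0, 0.45 * fs), btype="low", fs=fs, output="sos")
    env = signal.sosfiltfilt(sos, env)
    env = env - env.mean()
    denom = float(env @ env)
    if denom <= 0:
        return 0.0, 0.0
    lo, hi = int(round(0.6 * fs)), int(round(1.5 * fs))
    pre = int(round(0.25 * fs))
    if hi >= len(env):
        return 0.0, 0.0
    lags = np.arange(pre, hi + 1)
    ac = np.array([env[:-k] @ env[k:] for k in lags]) / denom
    in_band = lags >= lo
    k = int(np.argmax(np.where(in_band, ac, -np.inf)))
    valley = float(ac[: k + 1].min())
    return float(ac[k] - valley), float(lags[k] / fs)


def score_component(x: np.ndarray, fs: float, index: int = 0) -> ComponentScore:
    """Compute the fingerprint of one component series (>= 2 s of data)."""
    x = np.asarray(x, dtype=float).ravel()
    if len(x) < 2 * fs:
        raise ValueError(f"need at least 2 s of data ({int(2 * fs)} samples)")
    nperseg = min(len(x), int(2 * fs))
    f, p = signal.welch(x, fs=fs, nperseg=nperseg)
    nyq = fs / 2
    score = ComponentScore(
        index=index,
        kurtosis=float(stats.kurtosis(x, fisher=False)),
        lowfreq_ratio=_band_fraction(f, p, 1, 4),
        midband_ratio=_band_fraction(f, p, 8, 13),
        highfreq_ratio=_band_fraction(f, p, 20, min(60, nyq)),
        line_ratio=_band_fraction(f, p, 49, min(51, nyq)),
        periodicity=0.0,
        period_s=0.0,
    )
    score.periodicity, score.period_s = _cardiac_periodicity(x, fs)
    return score


def label_component(
    score: ComponentScore, thresholds: LabelThresholds | None = None
) -> str:
    """First-match decision list; total function, never raises."""
    th = thresholds or LabelThresholds()
    if score.line_ratio > th.line:
        return "line_noise"
    if score.highfreq_ratio > th.emg:
        return "muscle"
    if score.lowfreq_ratio > th.eog and score.kurtosis > th.kurtosis:
        return "eye"
    if (
        score.periodicity > th.heart
        and 0.6 <= score.period_s <= 1.5
        and score.kurtosis > th.kurtosis  # cardiac spike trains are impulsive
    ):
        return "heart"
    if score.midband_ratio > th.brain:
        return "brain"
    return "other"


def score_and_label(
    components: np.ndarray, fs: float, thresholds: LabelThresholds | None = None
) -> list[ComponentScore]:
    """Score and label every row of a components matrix."""
    out = []
    for j, c in enumerate(np.atleast_2d(components)):
        s = score_component(c, fs, index=j)
        s.label = label_component(s, thresholds)
        out.append(s)
    return out


def remove_and_backproject(
    components: np.ndarray,
    labels: list[str],
    mixing: np.ndarray,
    keep: set[str] = frozenset({"brain"}),
) -> np.ndarray:
    """Zero non-kept components and back-project through ``mixing``.

    ``components`` is r x n, ``mixing`` is channels x r; the output has
    shape channels x n.  Refuses to silently return zeros when every
    component would be removed.
    """
    components = np.asarray(components, dtype=float)
    mixing = np.asarray(mixing, dtype=float)
    if mixing.shape[1] != components.shape[0]:
        raise ValueError("mixing columns must match number of components")
    if len(labels) != components.shape[0]:
        raise ValueError("one label per component required")
    kept = [j for j, lab in enumerate(labels) if lab in keep]
    if not kept:
        raise ValueError(
            f"all components labelled outside keep set {sorted(keep)}; "
            "refusing to return an all-zero signal"
        )
    return mixing[:, kept] @ components[kept]
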
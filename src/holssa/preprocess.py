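"""Channel selection, resampling, filtering and bad-segment rejection.

Mirrors standard motor-imagery preprocessing: keep the motor-cortex
sensors (names containing the letter C on extended 10-20 montages —
note this deliberately also matches FC*/CP* electrodes), polyphase
anti-aliased downsampling (e.g. 500 -> 250 Hz), zero-phase Butterworth
filtering with a 1 Hz high-pass for decomposition-quality data, and
excision of flagged segments with a boundary event recorded at every
junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

__all__ = [
    "Recording",
    "select_motor_channels",
    "resample",
    "resample_recording",
    "highpass",
    "bandpass",
    "reject_segments",
    "flag_amplitude_segments",
]


@dataclass
class Recording:
    """Continuous multichannel recording.

    ``boundary_events`` are sample indices (in the current data) where
    a rejected segment was excised.
    """

    data: np.ndarray  # channels x samples
    fs: float
    channel_names: list[str]
    boundary_events: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("one name per channel required")
        if any(
            b2 <= b1 for b1, b2 in zip(self.boundary_events, self.boundary_events[1:])
        ) or any(not 0 <= b <= self.data.shape[1] for b in self.boundary_events):
            raise ValueError("boundary events must be strictly increasing and in range")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def select_motor_channels(rec: Recording) -> Recording:
    """Keep channels whose name contains the letter C (case-insensitive).

    On a 10-20-extended montage this selects the central strip
    (C*/FC*/CP*) covering the motor cortex.
    """
    if not rec.channel_names:
        raise ValueError("recording has no channel names")
    keep = [j for j, name in enumerate(rec.channel_names) if "c" in name.lower()]
    if not keep:
        raise ValueError("no motor channels: no channel name contains 'C'")
    return Recording(
        data=rec.data[keep],
        fs=rec.fs,
        channel_names=[rec.channel_names[j] for j in keep],
        boundary_events=list(rec.boundary_events),
    )


def resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase anti-aliased downsampling along the last axis."""
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be > 0")
    if fs_out > fs_in:
        raise ValueError("upsampling not supported (fs_out > fs_in)")
    if fs_out == fs_in:
        return np.asarray(x, dtype=float).copy()
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    return signal.resample_poly(np.asarray(x, dtype=float), frac.numerator, frac.denominator, axis=-1)


def resample_recording(rec: Recording, fs_out: float) -> Recording:
    data = resample(rec.data, rec.fs, fs_out)
    scale = fs_out / rec.fs
    return Recording(
        data=data,
        fs=fs_out,
        channel_names=list(rec.channel_names),
        boundary_events=sorted({min(int(round(b * scale)), data.shape[1]) for b in rec.boundary_events}),
    )


def _sos(kind: str, edges, fs: float):
    return signal.butter(4, edges, btype=kind, fs=fs, output="sos")


def highpass(x: np.ndarray, fs: float, cutoff: float = 1.0) -> np.ndarray:
    """Zero-phase (forward-backward) 4th-order Butterworth high-pass."""
    if not 0 < cutoff < fs / 2:
        raise ValueError(f"cutoff must be in (0, {fs / 2}), got {cutoff}")
    return signal.sosfiltfilt(_sos("high", cutoff, fs), np.asarray(x, dtype=float), axis=-1)


def bandpass(x: np.ndarray, fs: float, lo: float = 4.0, hi: float = 38.0) -> np.ndarray:
    """Zero-phase band-pass; 4-38 Hz default covers mu and beta rhythms."""
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band edges must satisfy 0 < {lo} < {hi} < {fs / 2}")
    return signal.sosfiltfilt(_sos("band", [lo, hi], fs), np.asarray(x, dtype=float), axis=-1)


def _normalize_intervals(intervals, n: int) -> list[tuple[int, int]]:
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    for a, b in ivs:
        if not 0 <= a < b <= n:
            raise ValueError(f"interval [{a}, {b}) outside data of length {n}")
    merged: list[tuple[int, int]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def reject_segments(rec: Recording, intervals) -> Recording:
    """Excise ``[start, stop)`` spans; record a boundary at each junction.

    Overlapping/adjacent spans are merged first; surviving spans are
    concatenated, so ``len(out) + total removed == len(in)``.
    """
    merged = _normalize_intervals(intervals, rec.n_samples)
    if not merged:
        return Recording(rec.data.copy(), rec.fs, list(rec.channel_names), list(rec.boundary_events))
    keep_mask = np.ones(rec.n_samples, dtype=bool)
    boundaries = []
    removed = 0
    for a, b in merged:
        keep_mask[a:b] = False
        boundaries.append(a - removed)
        removed += b - a
    return Recording(
        data=rec.data[:, keep_mask],
        fs=rec.fs,
        channel_names=list(rec.channel_names),
        boundary_events=sorted(set(boundaries)),
    )


def flag_amplitude_segments(
    rec: Recording, threshold: float, pad: float = 0.1
) -> list[tuple[int, int]]:
    """Programmatic stand-in for visual inspection: flag spans where any
    channel exceeds ``threshold`` in absolute value, padded by ``pad``
    seconds on each side."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    hot = np.any(np.abs(rec.data) > threshold, axis=0)
    if not hot.any():
        return []
    p = int(round(pad * rec.fs))
    idx = np.flatnonzero(hot)
    spans = []
    start = prev = idx[0]
    for j in idx[1:]:
        if j > prev + 1:
            spans.append((max(0, start - p), min(rec.n_samples, prev + 1 + p)))
            start = j
        prev = j
    spans.append((max(0, start - p), min(rec.n_samples, prev + 1 + p)))
    return _normalize_intervals(spans, rec.n_samples)
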
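"""Synthetic EEG: oscillatory brain sources, artifacts, mixtures, MI epochs.

Emulates the signal classes seen in scalp motor-imagery EEG: band-limited
rhythms (mu/alpha ~10 Hz, beta ~20 Hz) over pink-noise background, EOG
blinks (sparse smooth unipolar deflections, ~0.3 s), EMG bursts
(20-60 Hz band-passed noise under a burst envelope), quasi-periodic
biphasic ECG spikes (~1.2 beats/s), 50 Hz mains interference, linear
instantaneous mixing and additive Gaussian sensor noise.  Motor-imagery
epoch sets carry a class-specific event-related desynchronisation
(ERD): the 10 Hz rhythm is attenuated by ``1 - erd_depth`` on a fixed
per-class channel subset (left hand -> right-hemisphere channels,
right hand -> left, feet -> midline, rest -> none).

All randomness flows through one ``numpy`` Generator seeded per call:
identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "SourceSpec",
    "ArtifactSpec",
    "SyntheticRecording",
    "MIEpochSet",
    "generate_oscillation",
    "generate_artifact",
    "mix_recording",
    "generate_mi_dataset",
    "generate_contaminated_recording",
]

MI_CLASSES = ("left", "right", "feet", "rest")


@dataclass(frozen=True)
class SourceSpec:
    """Band-limited oscillation or pink-noise background source."""

    kind: str = "oscillation"  # or "pink_noise"
    center_freq: float = 10.0
    bandwidth: float = 0.0
    amplitude: float = 1.0
    seed: int = 0

    def validate(self, fs: float) -> None:
        if self.kind not in ("oscillation", "pink_noise"):
            raise ValueError(f"unknown source kind {self.kind!r}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.kind == "oscillation" and not 0 < self.center_freq < fs / 2:
            raise ValueError(
                f"center_freq {self.center_freq} outside (0, {fs / 2}) — aliasing"
            )


@dataclass(frozen=True)
class ArtifactSpec:
    """EOG blink / EMG burst / ECG spike / mains interference source."""

    kind: str
    rate: float = 0.0          # events per second (blink/burst/spike)
    amplitude: float = 1.0
    seed: int = 0
    line_freq: float = 50.0    # mains frequency; 50 Hz European default

    def validate(self) -> None:
        if self.kind not in ("eog_blink", "emg_burst", "ecg_spike", "line_noise"):
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass
class SyntheticRecording:
    """Mixed multichannel recording with its ground truth."""

    data: np.ndarray                  # channels x samples
    fs: float
    channel_names: list[str]
    ground_truth_sources: np.ndarray  # sources x samples
    mixing: np.ndarray                # channels x sources
    source_kinds: list[str] = field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0


@dataclass
class MIEpochSet:
    """Labelled 4-class motor-imagery trials."""

    epochs: np.ndarray  # trials x channels x samples
    labels: np.ndarray  # trial -> index into MI_CLASSES
    fs: float
    class_names: tuple[str, ...] = MI_CLASSES


def _check_duration(fs: float, duration: float) -> int:
    if fs <= 0:
        raise ValueError("fs must be > 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = int(round(duration * fs))
    if n < 8:
        raise ValueError("need at least 8 samples")
    return n


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / max(x.std(), 1e-30)


def generate_oscillation(spec: SourceSpec, fs: float, duration: float) -> np.ndarray:
    """One band-limited oscillatory (or pink-noise) source series.

    ``bandwidth == 0`` gives a pure random-phase sinusoid; otherwise the
    sinusoid is amplitude-modulated by a positive low-pass envelope of
    bandwidth ``bandwidth`` (unit mean), keeping the spectral peak at
    ``center_freq``.
    """
    n = _check_duration(fs, duration)
    spec.validate(fs)
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "pink_noise":
        return spec.amplitude * _pink_noise(rng, n)
    if spec.amplitude == 0:
        return np.zeros(n)
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    x = np.sin(2 * np.pi * spec.center_freq * t + phase)
    if spec.bandwidth > 0:
        sos = signal.butter(2, spec.bandwidth, btype="low", fs=fs, output="sos")
        env = signal.sosfiltfilt(sos, rng.standard_normal(n))
        env = 1 + env / max(3 * env.std(), 1e-30)  # positive, unit-mean
        x = x * np.clip(env, 0, None)
    return spec.amplitude * x


def _event_times(rng: np.random.Generator, rate: float, duration: float) -> np.ndarray:
    """Poisson event times in [0, duration)."""
    n_ev = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0, duration, size=n_ev))


def generate_artifact(spec: ArtifactSpec, fs: float, duration: float) -> np.ndarray:
    """One artifact series of ``duration * fs`` samples."""
    n = _check_duration(fs, duration)
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t = np.arange(n) / fs
    x = np.zeros(n)

    if spec.kind == "line_noise":
        return spec.amplitude * np.sin(2 * np.pi * spec.line_freq * t + rng.uniform(0, 2 * np.pi))

    if spec.kind == "eog_blink":
        width = 0.3  # seconds; smooth unipolar squared-sine pulse
        m = int(round(width * fs))
        pulse = np.sin(np.pi * np.arange(m) / m) ** 2
        for t0 in _event_times(rng, spec.rate, duration - width):
            j = int(round(t0 * fs))
            x[j : j + m] += spec.amplitude * pulse[: n - j]
        return x

    if spec.kind == "emg_burst":
        if spec.rate == 0 or spec.amplitude == 0:
            return x
        lo, hi = 20.0, min(60.0, 0.45 * fs)
        sos = signal.butter(4, [lo, hi], btype="band", fs=fs, output="sos")
        noise = signal.sosfiltfilt(sos, rng.standard_normal(n))
        noise /= max(noise.std(), 1e-30)
        width = 0.5
        m = int(round(width * fs))
        env = np.zeros(n)
        for t0 in _event_times(rng, spec.rate, duration - width):
            j = int(round(t0 * fs))
            env[j : j + m] = np.maximum(env[j : j + m], np.hanning(m)[: n - j])
        return spec.amplitude * env * noise

    # ecg_spike: biphasic pulses at quasi-regular intervals (~2% jitter)
    if spec.rate == 0 or spec.amplitude == 0:
        return x
    period = 1.0 / spec.rate
    sigma = 0.02  # seconds; spike half-width
    m = int(round(8 * sigma * fs))
    tt = (np.arange(m) - m / 2) / fs
    pulse = -tt / sigma * np.exp(0.5 - 0.5 * (tt / sigma) ** 2)  # unit peak
    t0 = rng.uniform(0, period)
    while t0 < duration - 8 * sigma:
        j = int(round(t0 * fs))
        x[j : j + m] += spec.amplitude * pulse[: n - j]
        t0 += period * (1 + 0.02 * rng.standard_normal())
    return x


def mix_recording(
    sources: list[np.ndarray],
    artifacts: list[np.ndarray],
    mixing: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    fs: float = 250.0,
    channel_names: list[str] | None = None,
    source_kinds: list[str] | None = None,
) -> SyntheticRecording:
    """Linear instantaneous mixture plus Gaussian sensor noise.

    ``mixing`` has one column per stacked source/artifact series; the
    ground truth (sources, mixing) is stored for later evaluation.
    """
    series = list(sources) + list(artifacts)
    if not series:
        raise ValueError("need at least one source")
    lengths = {len(s) for s in series}
    if len(lengths) != 1:
        raise ValueError(f"all series must have equal length, got {sorted(lengths)}")
    S = np.vstack(series)
    mixing = np.asarray(mixing, dtype=float)
    if mixing.ndim != 2 or mixing.shape[1] != S.shape[0]:
        raise ValueError(
            f"mixing must be channels x {S.shape[0]}, got {mixing.shape}"
        )
    rng = np.random.default_rng(seed)
    data = mixing @ S
    if noise_sd > 0:
        data = data + rng.normal(0, noise_sd, size=data.shape)
    names = channel_names or [f"C{j + 1}" for j in range(mixing.shape[0])]
    kinds = source_kinds or (
        ["source"] * len(sources) + ["artifact"] * len(artifacts)
    )
    return SyntheticRecording(
        data=data,
        fs=fs,
        channel_names=names,
        ground_truth_sources=S,
        mixing=mixing,
        source_kinds=kinds,
        noise_sd=noise_sd,
        seed=seed,
    )


def generate_contaminated_recording(
    seed: int = 0,
    fs: float = 250.0,
    duration: float = 30.0,
    n_channels: int = 4,
    noise_sd: float = 0.1,
) -> SyntheticRecording:
    """Standard contaminated test recording: brain rhythms + EOG/EMG/mains.

    Brain content: one 10 Hz mu/alpha rhythm (bandwidth 2 Hz, amp 1)
    and one pink-noise background (amp 0.5) per recording; artifacts:
    EOG blinks (0.2 /s, amp 8 — blinks dwarf cortical rhythms), EMG
    bursts (0.5 /s, amp 2.5), 50 Hz mains (amp 1.5).  Mixing columns
    are random-signed with unit-scale entries for brain sources; the
    EOG column decays toward posterior channels (frontal dominance).
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=8)
    alpha = generate_oscillation(
        SourceSpec("oscillation", 10.0, 2.0, 1.0, int(sub[0])), fs, duration
    )
    pink = generate_oscillation(
        SourceSpec("pink_noise", amplitude=0.5, seed=int(sub[1])), fs, duration
    )
    eog = generate_artifact(ArtifactSpec("eog_blink", 0.2, 8.0, int(sub[2])), fs, duration)
    emg = generate_artifact(ArtifactSpec("emg_burst", 0.5, 2.5, int(sub[3])), fs, duration)
    line = generate_artifact(ArtifactSpec("line_noise", 0.0, 1.5, int(sub[4])), fs, duration)
    n_src = 5
    mixing = rng.uniform(0.5, 1.5, size=(n_channels, n_src)) * rng.choice(
        [-1.0, 1.0], size=(n_channels, n_src)
    )
    mixing[:, 2] = 8.0 ** -np.linspace(0, 1, n_channels) * np.abs(mixing[:, 2])  # EOG frontal falloff
    mixing[:, 4] = np.abs(mixing[:, 4])  # mains couples with one sign
    return mix_recording(
        [alpha, pink],
        [eog, emg, line],
        mixing,
        noise_sd=noise_sd,
        seed=int(sub[5]),
        fs=fs,
        source_kinds=["brain", "brain", "eye", "muscle", "line_noise"],
    )


def _class_channels(n_channels: int) -> dict[str, np.ndarray]:
    """Fixed ERD topography: quarter-splits of the channel list.

    First quarter = right hemisphere (left-hand imagery), second = left
    hemisphere (right-hand), third = midline (feet), rest = no ERD.
    """
    if n_channels < 4:
        raise ValueError("need at least 4 channels for disjoint class topographies")
    q = n_channels // 4
    idx = np.arange(n_channels)
    return {
        "left": idx[:q],
        "right": idx[q : 2 * q],
        "feet": idx[2 * q : 3 * q],
        "rest": idx[:0],
    }


def generate_mi_dataset(
    n_per_class: int = 100,
    fs: float = 250.0,
    n_channels: int = 8,
    epoch_len: float = 2.0,
    erd_depth: float = 0.8,
    seed: int = 0,
) -> MIEpochSet:
    """Balanced 4-class MI epochs with class-specific 10 Hz ERD.

    Every channel carries a 10 Hz rhythm (amp 1, random phase per
    trial/channel) over pink noise (amp 0.5) and white sensor noise
    (sd 0.2); for a trial of class c the rhythm amplitude on that
    class's channel subset is multiplied by ``1 - erd_depth``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not 0 <= erd_depth <= 1:
        raise ValueError("erd_depth must be in [0, 1]")
    topo = _class_channels(n_channels)
    n_samp = int(round(epoch_len * fs))
    rng = np.random.default_rng(seed)
    t = np.arange(n_samp) / fs
    n_trials = 4 * n_per_class
    labels = np.repeat(np.arange(4), n_per_class)
    rng.shuffle(labels)
    epochs = np.zeros((n_trials, n_channels, n_samp))
    for k in range(n_trials):
        attn = topo[MI_CLASSES[labels[k]]]
        for ch in range(n_channels):
            amp = (1 - erd_depth) if ch in attn else 1.0
            rhythm = amp * np.sin(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))
            background = 0.5 * _pink_noise(rng, n_samp)
            epochs[k, ch] = rhythm + background + 0.2 * rng.standard_normal(n_samp)
    return MIEpochSet(epochs=epochs, labels=labels, fs=fs)
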
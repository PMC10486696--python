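"""Pipeline configuration: plain key=value text with strict validation.

Unknown keys are rejected and every numeric field is range-checked
before any data is touched, so a bad configuration fails fast.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # sampling / filtering
    fs_out: float = 250.0
    highpass_hz: float = 1.0
    bandpass_lo: float = 4.0
    bandpass_hi: float = 38.0
    # embedding / decomposition
    window: int = 25           # samples; ~0.1 s at 250 Hz
    depth: int = 0             # 0 -> floor(L/2)
    energy: float = 0.99
    max_rank: int = 8
    group_threshold: float = 0.9
    # ORICA
    l_r: float = 0.005
    nonlinearity: str = "tanh"
    n_passes: int = 3
    # artifact thresholds
    theta_line: float = 0.5
    theta_emg: float = 0.5
    theta_eog: float = 0.4
    theta_kurtosis: float = 5.0
    theta_heart: float = 0.3
    theta_brain: float = 0.3
    # CSP / classifier
    n_pairs: int = 3
    hidden: int = 64
    adaptation_rate: float = 1.0
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        checks = [
            (self.fs_out > 0, "fs_out must be > 0"),
            (0 < self.highpass_hz < self.fs_out / 2, "highpass_hz out of range"),
            (0 < self.bandpass_lo < self.bandpass_hi < self.fs_out / 2,
             "bandpass edges must satisfy 0 < lo < hi < fs/2"),
            (self.window >= 2, "window must be >= 2 samples"),
            (self.depth >= 0, "depth must be >= 0 (0 = automatic)"),
            (0 < self.energy <= 1, "energy must be in (0, 1]"),
            (self.max_rank >= 1, "max_rank must be >= 1"),
            (0 < self.group_threshold <= 1, "group_threshold must be in (0, 1]"),
            (0 < self.l_r < 1, "l_r must be in (0, 1)"),
            (self.nonlinearity in ("tanh", "cubic"), "nonlinearity must be tanh|cubic"),
            (self.n_passes >= 1, "n_passes must be >= 1"),
            (self.n_pairs >= 1, "n_pairs must be >= 1"),
            (self.hidden >= 1, "hidden must be >= 1"),
            (self.adaptation_rate > 0, "adaptation_rate must be > 0"),
        ]
        for th in ("theta_line", "theta_emg", "theta_eog", "theta_heart", "theta_brain"):
            checks.append((getattr(self, th) > 0, f"{th} must be > 0"))
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")
        return self

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def load_config(path=None, **overrides) -> PipelineConfig:
    """Build a validated config from an optional key=value file + overrides."""
    values: dict = {}
    if path is not None:
        text = Path(path).read_text()
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            k, v = (s.strip() for s in line.split("=", 1))
            values[k] = v
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name: f.type for f in fields(PipelineConfig)}
    unknown = set(values) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    typed = {}
    defaults = PipelineConfig()
    for k, v in values.items():
        cur = getattr(defaults, k)
        if isinstance(cur, bool):
            typed[k] = str(v).lower() in ("1", "true", "yes")
        elif isinstance(cur, int):
            typed[k] = int(v)
        elif isinstance(cur, float):
            typed[k] = float(v)
        else:
            typed[k] = str(v)
    return PipelineConfig(**typed).validate()
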
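"""Reading and writing recordings, epochs, features and reports.

Canonical on-disk format is delimited text: CSV with channels as
columns, a header row of channel names, and ``#``-prefixed provenance
comment lines (stage, seed, config hash) at the top.  The sampling
rate and other metadata live in a ``<file>.meta`` sidecar of
``key=value`` lines.  EDF files are read through ``mne`` when it is
installed; EDF writing is not supported.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Recording
from .synthetic import MIEpochSet

__all__ = [
    "read_recording",
    "write_recording",
    "write_epochs",
    "read_epochs",
    "write_table",
    "provenance_header",
]


def provenance_header(stage: str, seed=None, config_hash: str | None = None) -> list[str]:
    parts = [f"stage={stage}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash:
        parts.append(f"config={config_hash}")
    return ["# holssa " + " ".join(parts)]


def config_hash(d: dict) -> str:
    text = ";".join(f"{k}={d[k]}" for k in sorted(d))
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta")


def _write_meta(path: Path, meta: dict) -> None:
    _meta_path(path).write_text(
        "".join(f"{k}={v}\n" for k, v in meta.items())
    )


def _read_meta(path: Path) -> dict:
    mp = _meta_path(path)
    if not mp.exists():
        return {}
    out = {}
    for line in mp.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#") and "=" in line:
            k, v = line.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def write_recording(
    rec: Recording, path, stage: str = "recording", seed=None, cfg_hash=None
) -> Path:
    """CSV: provenance comments, channel-name header, channels as columns."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\n".join(provenance_header(stage, seed, cfg_hash)) + "\n")
        pd.DataFrame(rec.data.T, columns=rec.channel_names).to_csv(fh, index=False)
    meta = {"fs": rec.fs}
    if rec.boundary_events:
        meta["boundary_events"] = ",".join(str(b) for b in rec.boundary_events)
    if seed is not None:
        meta["seed"] = seed
    _write_meta(path, meta)
    return path


def read_recording(path, format: str = "auto", fs: float | None = None) -> Recording:
    """Read an EDF or CSV recording.

    CSV needs the sampling rate from the ``.meta`` sidecar or the
    ``fs`` argument; a missing rate is an explicit error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover
            raise RuntimeError("reading EDF requires the 'mne' package") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return Recording(
            data=raw.get_data(),
            fs=float(raw.info["sfreq"]),
            channel_names=list(raw.ch_names),
        )
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")
    meta = _read_meta(path)
    if fs is None:
        if "fs" not in meta:
            raise ValueError(
                f"{path}: sampling rate not given and no fs in {_meta_path(path).name}"
            )
        fs = float(meta["fs"])
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
    boundaries = [
        int(b) for b in meta.get("boundary_events", "").split(",") if b.strip()
    ]
    return Recording(
        data=df.to_numpy(dtype=float).T,
        fs=fs,
        channel_names=[str(c) for c in df.columns],
        boundary_events=boundaries,
    )


def write_epochs(eset: MIEpochSet, path, stage="epochs", seed=None, cfg_hash=None) -> Path:
    """Long-format CSV: trial, label, channel, then one column per sample."""
    path = Path(path)
    n_tr, n_ch, n_samp = eset.epochs.shape
    rows = eset.epochs.reshape(n_tr * n_ch, n_samp)
    df = pd.DataFrame(rows, columns=[f"s{j}" for j in range(n_samp)])
    df.insert(0, "channel", np.tile(np.arange(n_ch), n_tr))
    df.insert(0, "label", np.repeat(eset.labels, n_ch))
    df.insert(0, "trial", np.repeat(np.arange(n_tr), n_ch))
    with open(path, "w") as fh:
        fh.write("\n".join(provenance_header(stage, seed, cfg_hash)) + "\n")
        df.to_csv(fh, index=False)
    _write_meta(path, {"fs": eset.fs, "classes": ",".join(eset.class_names)})
    return path


def read_epochs(path) -> MIEpochSet:
    path = Path(path)
    meta = _read_meta(path)
    if "fs" not in meta:
        raise ValueError(f"{path}: no fs in sidecar metadata")
    df = pd.read_csv(path, comment="#")
    trials = np.sort(df["trial"].unique())
    n_ch = df["channel"].nunique()
    sample_cols = [c for c in df.columns if c.startswith("s") and c[1:].isdigit()]
    epochs = np.empty((len(trials), n_ch, len(sample_cols)))
    labels = np.empty(len(trials), dtype=int)
    for k, tr in enumerate(trials):
        sub = df[df["trial"] == tr].sort_values("channel")
        epochs[k] = sub[sample_cols].to_numpy(dtype=float)
        labels[k] = int(sub["label"].iloc[0])
    classes = tuple(meta.get("classes", "left,right,feet,rest").split(","))
    return MIEpochSet(epochs=epochs, labels=labels, fs=float(meta["fs"]), class_names=classes)


def write_table(df: pd.DataFrame, path, stage: str, seed=None, cfg_hash=None) -> Path:
    """Generic provenance-headed CSV table."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\n".join(provenance_header(stage, seed, cfg_hash)) + "\n")
        df.to_csv(fh, index=False)
    return path
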
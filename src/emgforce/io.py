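"""Delimited-text recording I/O and config (de)serialization.

Recordings are stored as CSV with header ``time,<label1>,...,<labelN>,force``
(one row per sample) plus a YAML sidecar ``<path>.meta.yaml`` holding the
sampling rate and, for synthetic data, the full generator config for
provenance.
"""

from __future__ import annotations

from dataclasses import asdict, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import Recording, SynthConfig

__all__ = ["write_recording", "read_recording", "sidecar_path",
           "synth_config_to_dict", "synth_config_from_dict"]


def sidecar_path(path) -> Path:
    return Path(str(path) + ".meta.yaml")


def _tuplify(cfg_cls, d: dict) -> dict:
    """YAML has no tuples; convert list values back for tuple-typed fields."""
    out = dict(d)
    for f in fields(cfg_cls):
        if f.name in out and isinstance(out[f.name], list):
            out[f.name] = tuple(out[f.name])
    return out


def synth_config_to_dict(cfg: SynthConfig) -> dict:
    return asdict(cfg)


def synth_config_from_dict(d: dict) -> SynthConfig:
    return SynthConfig(**_tuplify(SynthConfig, d))


def write_recording(recording: Recording, path) -> Path:
    """Write CSV + provenance sidecar; returns the CSV path."""
    path = Path(path)
    t = np.arange(recording.n_samples) / recording.fs
    df = pd.DataFrame({"time": t})
    for i, label in enumerate(recording.labels):
        df[label] = recording.signals[:, i]
    df["force"] = recording.force
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    meta = {"fs": recording.fs, "labels": list(recording.labels)}
    if recording.truth is not None:
        meta["synth_config"] = synth_config_to_dict(recording.truth)
    sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_recording(path) -> Recording:
    """Read a CSV written by :func:`write_recording` (sidecar optional)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols[0] != "time" or cols[-1] != "force":
        raise ValueError("expected columns time,<channels...>,force")
    labels = tuple(cols[1:-1])
    truth = None
    fs = None
    sp = sidecar_path(path)
    if sp.exists():
        meta = yaml.safe_load(sp.read_text())
        fs = float(meta["fs"])
        if "synth_config" in meta:
            truth = synth_config_from_dict(meta["synth_config"])
    if fs is None:
        dt = np.diff(df["time"].to_numpy()[:2])[0]
        fs = 1.0 / dt
    return Recording(signals=df[list(labels)].to_numpy(),
                     force=df["force"].to_numpy(), fs=fs, labels=labels,
                     truth=truth)
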
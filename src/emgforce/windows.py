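"""Sliding-window dataset construction from a Recording."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import Recording

__all__ = ["WindowSpec", "WindowedDataset", "build_windows"]


@dataclass(frozen=True)
class WindowSpec:
    """How the continuous multi-channel stream becomes fixed-length samples.

    ``per_channel`` windows a single channel (``channel`` index, default 0),
    giving rows of ``window_len`` samples; ``stacked`` concatenates all
    channels channel-major, giving rows of ``n_channels * window_len``.
    """

    window_len: int = 200   # samples (200 ms at 1 kHz)
    stride: int = 100       # samples (50% overlap)
    channel_mode: str = "per_channel"
    channel: int = 0        # used in per_channel mode

    def __post_init__(self) -> None:
        if not (0 < self.stride <= self.window_len):
            raise ValueError("require 0 < stride <= window_len")
        if self.channel_mode not in ("per_channel", "stacked"):
            raise ValueError("channel_mode must be 'per_channel' or 'stacked'")


@dataclass
class WindowedDataset:
    """Per-window input rows paired with per-window mean-force targets."""

    X: np.ndarray                   # (n_windows, d)
    y: np.ndarray                   # (n_windows,)
    window_len: int
    stride: int
    n_channels: int                 # channels represented in each row
    labels: tuple[str, ...] = ()
    kind: str = "raw"               # raw | pca | kpca | features

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.X) != len(self.y):
            raise ValueError("X and y must have the same number of rows")

    def __len__(self) -> int:
        return len(self.X)

    def as_sequences(self) -> np.ndarray:
        """Rows reshaped to (n, channels, length) for sequence models."""
        if self.kind == "raw":
            return self.X.reshape(len(self.X), self.n_channels, self.window_len)
        return self.X[:, None, :]   # reduced/feature rows: one channel

    def subset(self, idx: np.ndarray) -> "WindowedDataset":
        return WindowedDataset(self.X[idx], self.y[idx], self.window_len,
                               self.stride, self.n_channels, self.labels, self.kind)


def build_windows(recording: Recording, spec: WindowSpec) -> WindowedDataset:
    """Slice a recording into overlapping windows.

    The number of windows is ``floor((T - window_len) / stride) + 1``; each
    window's regression target is the mean force over its samples.
    """
    T = recording.n_samples
    if T == 0:
        raise ValueError("empty recording")
    L, s = spec.window_len, spec.stride
    if L > T:
        raise ValueError(f"window_len={L} exceeds recording length {T}")
    n = (T - L) // s + 1
    starts = s * np.arange(n)
    idx = starts[:, None] + np.arange(L)[None, :]

    if spec.channel_mode == "per_channel":
        sig = recording.signals[:, spec.channel]
        X = sig[idx]
        n_ch = 1
        labels = (recording.labels[spec.channel],)
    else:
        # channel-major: row = [ch0 window, ch1 window, ...]
        wins = recording.signals.T[:, idx]          # (C, n, L)
        X = wins.transpose(1, 0, 2).reshape(n, -1)
        n_ch = recording.n_channels
        labels = recording.labels
    y = recording.force[idx].mean(axis=1)
    return WindowedDataset(X=X, y=y, window_len=L, stride=s, n_channels=n_ch,
                           labels=tuple(labels), kind="raw")
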
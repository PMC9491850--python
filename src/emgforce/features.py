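"""Classical per-window time-domain EMG features: MAV, VAR, ZC, WA.

Standard EMG-literature definitions: mean absolute value, sample variance
(denominator L-1), zero-crossing count with an amplitude-step threshold, and
Willison amplitude (count of successive differences exceeding a threshold).
These serve as hand-crafted baselines against learned feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .windows import WindowedDataset

__all__ = ["FeatureSpec", "mav", "var", "zero_crossings", "willison_amplitude",
           "featurize", "FEATURES"]

FEATURES = ("MAV", "VAR", "ZC", "WA")


@dataclass(frozen=True)
class FeatureSpec:
    """Which features to compute and their amplitude thresholds.

    ``wa_threshold=None`` uses the adaptive default 0.05 x window RMS.
    """

    features: tuple[str, ...] = FEATURES
    zc_threshold: float = 0.0
    wa_threshold: float | None = None

    def __post_init__(self) -> None:
        for f in self.features:
            if f not in FEATURES:
                raise ValueError(f"unknown feature {f!r}; valid: {FEATURES}")
        if not np.isfinite(self.zc_threshold) or self.zc_threshold < 0:
            raise ValueError("zc_threshold must be finite and >= 0")
        if self.wa_threshold is not None and (
                not np.isfinite(self.wa_threshold) or self.wa_threshold < 0):
            raise ValueError("wa_threshold must be finite and >= 0")


def mav(window: np.ndarray) -> float:
    """Mean absolute value (1/L) sum |x_i|."""
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise ValueError("empty window")
    return float(np.mean(np.abs(w)))


def var(window: np.ndarray) -> float:
    """Sample variance with denominator L-1 (0 for a length-1 window)."""
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise ValueError("empty window")
    if w.size == 1:
        return 0.0
    return float(np.var(w, ddof=1))


def zero_crossings(window: np.ndarray, threshold: float = 0.0) -> int:
    """Sign changes between consecutive samples with |x_i - x_{i+1}| > threshold."""
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise ValueError("empty window")
    sign_change = np.signbit(w[:-1]) != np.signbit(w[1:])
    big_step = np.abs(np.diff(w)) > threshold
    return int(np.count_nonzero(sign_change & big_step))


def willison_amplitude(window: np.ndarray, threshold: float = 0.0) -> int:
    """Count of successive differences with |x_i - x_{i+1}| > threshold."""
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise ValueError("empty window")
    return int(np.count_nonzero(np.abs(np.diff(w)) > threshold))


def _one(window: np.ndarray, name: str, spec: FeatureSpec) -> float:
    if name == "MAV":
        return mav(window)
    if name == "VAR":
        return var(window)
    if name == "ZC":
        return float(zero_crossings(window, spec.zc_threshold))
    wa_thr = spec.wa_threshold
    if wa_thr is None:
        wa_thr = 0.05 * float(np.sqrt(np.mean(window ** 2)))
    return float(willison_amplitude(window, wa_thr))


def featurize(dataset: WindowedDataset, spec: FeatureSpec = FeatureSpec()
              ) -> WindowedDataset:
    """Replace raw window rows by per-channel time-domain features.

    Row order is preserved; columns are ordered feature-major then channel
    (``<feature>_<channel>``), matching :func:`feature_names`.
    """
    seqs = dataset.as_sequences()               # (n, C, L)
    n, C, _ = seqs.shape
    cols = []
    for fname in spec.features:
        for c in range(C):
            cols.append([_one(seqs[i, c], fname, spec) for i in range(n)])
    X = np.array(cols, dtype=float).T
    return WindowedDataset(X=X, y=dataset.y.copy(), window_len=dataset.window_len,
                           stride=dataset.stride, n_channels=1,
                           labels=dataset.labels, kind="features")


def feature_names(spec: FeatureSpec, labels) -> list[str]:
    return [f"{f}_{ch}" for f in spec.features for ch in labels]


def write_feature_table(dataset: WindowedDataset, spec: FeatureSpec, path) -> None:
    """Featurize and write a delimited table with ``<feature>_<channel>`` columns."""
    import pandas as pd

    out = featurize(dataset, spec)
    df = pd.DataFrame(out.X, columns=feature_names(spec, dataset.labels))
    df["force"] = out.y
    df.to_csv(path, index=False)
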
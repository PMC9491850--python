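"""Performance indices, SNR-controlled noise injection and spectral analysis.

The regression indices are mean squared error, its square root (RMS error),
mean absolute error (MAVE) and the Pearson correlation between measured and
predicted force expressed in percent.  Spectra are averaged modified
periodograms (Welch, 1 s segments, 50% overlap, Hann taper).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

__all__ = ["Metrics", "Spectrum", "mse", "metrics_suite", "add_noise_snr",
           "spectrum", "detect_interference"]


@dataclass(frozen=True)
class Metrics:
    """Error indices between a measured and a predicted force trace."""

    mse: float      # N^2
    rms: float      # N, sqrt(mse)
    mave: float     # N, mean |error|
    rho: float      # percent Pearson correlation; NaN if undefined


def mse(measured, predicted) -> float:
    """Mean squared error (1/N) sum (x1_i - x2_i)^2."""
    a = np.asarray(measured, dtype=float)
    b = np.asarray(predicted, dtype=float)
    if a.shape != b.shape:
        raise ValueError("measured and predicted must have equal length")
    if a.size == 0:
        raise ValueError("need at least one sample")
    return float(np.mean((a - b) ** 2))


def metrics_suite(measured, predicted) -> Metrics:
    """MSE, RMS error, MAVE and Pearson correlation (percent).

    A constant measured vector leaves the correlation undefined; it is
    reported as NaN with a warning.
    """
    a = np.asarray(measured, dtype=float)
    b = np.asarray(predicted, dtype=float)
    m = mse(a, b)
    mave = float(np.mean(np.abs(a - b)))
    if a.std() == 0 or b.std() == 0:
        warnings.warn("correlation undefined for constant input; reporting NaN",
                      stacklevel=2)
        rho = float("nan")
    else:
        rho = 100.0 * float(stats.pearsonr(a, b).statistic)
    return Metrics(mse=m, rms=float(np.sqrt(m)), mave=mave, rho=rho)


def add_noise_snr(signal, snr_db: float, seed: int) -> np.ndarray:
    """Additive white Gaussian noise at a prescribed signal-to-noise ratio.

    The noise is scaled so 10*log10(P_signal / P_noise) = snr_db, with
    P_signal the mean square of the input.
    """
    x = np.asarray(signal, dtype=float)
    p_signal = float(np.mean(x ** 2))
    p_noise = p_signal / 10.0 ** (snr_db / 10.0)
    rng = np.random.default_rng(seed)
    return x + np.sqrt(p_noise) * rng.standard_normal(x.shape)


@dataclass(frozen=True)
class Spectrum:
    frequencies: np.ndarray     # Hz, in [0, fs/2]
    power: np.ndarray           # density
    fs: float


def spectrum(signal, fs: float, segment_seconds: float = 1.0) -> Spectrum:
    """Averaged modified periodogram (Welch) power spectral density."""
    x = np.asarray(signal, dtype=float)
    nperseg = min(int(round(segment_seconds * fs)), len(x))
    f, p = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                     noverlap=nperseg // 2)
    return Spectrum(frequencies=f, power=p, fs=fs)


def detect_interference(spec: Spectrum, target_hz: float, tol_hz: float = 1.0,
                        factor: float = 3.0) -> tuple[bool, tuple[float, float]]:
    """Is there a spectral line within +/- tol of the target frequency?

    Detection requires the maximum in the target band to be a local maximum
    of the spectrum and to exceed ``factor`` times the median power of the
    surrounding neighborhood (within 20 Hz, excluding the target band).
    Returns (detected, (peak_frequency, peak_power)).
    """
    f, p = spec.frequencies, spec.power
    band = np.abs(f - target_hz) <= tol_hz
    if not band.any():
        raise ValueError("target band outside the spectrum")
    i_peak = np.flatnonzero(band)[np.argmax(p[band])]
    peak = (float(f[i_peak]), float(p[i_peak]))
    local_max = (p[i_peak] >= p[max(i_peak - 1, 0)]
                 and p[i_peak] >= p[min(i_peak + 1, len(p) - 1)])
    neigh = (np.abs(f - target_hz) <= 20.0) & ~band
    if not neigh.any():
        return False, peak
    detected = bool(local_max and p[i_peak] > factor * np.median(p[neigh]))
    return detected, peak
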
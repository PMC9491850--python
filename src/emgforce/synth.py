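"""Seeded synthetic surface-EMG and force generation.

Emulates multi-channel upper-arm sEMG recorded at 1 kHz together with a
synchronized load-cell force trace, for four isometric elbow/forearm tasks
(flexion, extension, pronation, supination).  Each muscle channel is an
activation-envelope-modulated motor-unit action-potential (MUAP) train -- a
small pool of motor units firing tonically at regular physiological rates,
each with a stereotyped wavelet-shaped action potential -- plus a weak
broadband stochastic component, giving power concentrated in the 20-150 Hz
band.  Channels are contaminated by a 50 Hz powerline sinusoid, a narrowband
~110 Hz ECG-like artifact and additive white noise at a configurable SNR.
The force trace is a saturating nonlinear function of the per-muscle
activations with a known (planted) dominant muscle per task, so that
downstream variable-importance procedures can be validated against ground
truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "SynthConfig",
    "Recording",
    "TASKS",
    "DEFAULT_LABELS",
    "task_weights",
    "generate_activation",
    "generate_recording",
    "generate_task_suite",
]

DEFAULT_LABELS: tuple[str, ...] = ("BB", "TB", "BR", "BRD")

# Planted per-task force weights for (BB, TB, BR, BRD) =
# (biceps brachii, triceps brachii, brachialis, brachioradialis).
# Exactly one maximal entry per task: flexion -> BB, extension -> TB,
# pronation -> BRD, supination -> BR.  Secondary weights follow rough
# physiological synergy (e.g. biceps assists supination).
_TASK_WEIGHTS: Mapping[str, tuple[float, ...]] = {
    "flexion": (1.0, 0.15, 0.45, 0.30),
    "extension": (0.20, 1.0, 0.15, 0.25),
    "pronation": (0.30, 0.20, 0.25, 1.0),
    "supination": (0.45, 0.15, 1.0, 0.30),
}

TASKS: tuple[str, ...] = tuple(_TASK_WEIGHTS)


def task_weights(task: str) -> tuple[float, ...]:
    """Default per-channel force weights for a task (order ``DEFAULT_LABELS``)."""
    try:
        return _TASK_WEIGHTS[task]
    except KeyError:
        raise ValueError(
            f"unknown task {task!r}; valid tasks are {sorted(_TASK_WEIGHTS)}"
        ) from None


def _stream(seed: int, tag: str) -> np.random.Generator:
    """Independent, platform-stable substream keyed by an integer seed and a tag.

    Keying per-channel streams by the channel *label* makes the generator
    equivariant under joint permutation of (labels, weight_vector).
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(tag.encode())]))


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic recording.

    Amplitudes are relative to the unit-variance EMG carrier; ``snr_db`` sets
    the power ratio between the composite signal (EMG + artifacts) and the
    additive white noise floor.
    """

    duration: float = 60.0          # s
    fs: float = 1000.0              # Hz
    n_channels: int = 4
    channel_labels: tuple[str, ...] = DEFAULT_LABELS
    task: str = "flexion"
    weight_vector: tuple[float, ...] | None = None   # defaults to task_weights(task)
    powerline_hz: float = 50.0
    ecg_artifact_hz: float = 110.0
    powerline_amplitude: float = 0.10
    ecg_amplitude: float = 0.05
    snr_db: float = 20.0
    bout_on: float = 2.0            # s of effort
    bout_off: float = 2.0           # s of rest
    ramp: float = 0.3               # s raised-cosine envelope edge
    carrier_band: tuple[float, float] = (20.0, 150.0)
    n_motor_units: int = 5          # tonically firing units per muscle
    muap_center_range: tuple[float, float] = (60.0, 120.0)  # Hz, MUAP spectral peak
    carrier_noise_frac: float = 0.0   # optional broadband stochastic EMG fraction
    channel_corr: float = 0.2       # shared-carrier fraction between muscles
    force_scale: float = 20.0       # N at full simultaneous activation
    force_noise: float = 0.01       # fraction of force_scale (load-cell noise)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.fs <= 0:
            raise ValueError("duration and fs must be positive")
        if self.n_channels != len(self.channel_labels):
            raise ValueError("channel_labels length must equal n_channels")
        w = self.weights
        if len(w) != self.n_channels:
            raise ValueError("weight_vector must have n_channels entries")
        if any(x < 0 for x in w):
            raise ValueError("weights must be non-negative")
        if sum(1 for x in w if x == max(w)) != 1:
            raise ValueError("exactly one maximal weight (dominant muscle) required")
        f_max = max(self.carrier_band[1], self.powerline_hz, self.ecg_artifact_hz)
        if self.fs <= 2 * f_max:
            raise ValueError(f"fs={self.fs} must exceed twice the maximum generated "
                             f"frequency ({f_max} Hz)")
        if not (self.powerline_amplitude >= 0 and self.ecg_amplitude >= 0):
            raise ValueError("artifact amplitudes must be >= 0")

    @property
    def weights(self) -> tuple[float, ...]:
        if self.weight_vector is not None:
            return tuple(self.weight_vector)
        return task_weights(self.task)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass
class Recording:
    """Synchronized multi-channel sEMG + force trace."""

    signals: np.ndarray             # (T, C), arbitrary amplitude units
    force: np.ndarray               # (T,), N
    fs: float
    labels: tuple[str, ...]
    truth: SynthConfig | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a (time, channels) matrix")
        if len(self.force) != len(self.signals):
            raise ValueError("signals and force must have identical length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.labels) != self.signals.shape[1]:
            raise ValueError("labels length must equal channel count")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[0]

    @property
    def n_channels(self) -> int:
        return self.signals.shape[1]

    def channel(self, label: str) -> np.ndarray:
        return self.signals[:, self.labels.index(label)]


def _bout_shape(duration: float, fs: float, on: float, off: float,
                ramp: float) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Alternating rest/effort schedule starting at rest.

    Returns the unit-amplitude effort shape (zero during rest, raised-cosine
    ramps of length ``ramp`` at bout edges) and per-bout (index, start, stop)
    sample spans.
    """
    n = int(round(duration * fs))
    shape = np.zeros(n)
    spans: list[tuple[int, int, int]] = []
    period = on + off
    b = 0
    t0 = off
    while t0 < duration:
        start = int(round(t0 * fs))
        stop = min(int(round((t0 + on) * fs)), n)
        seg = stop - start
        if seg > 0:
            prof = np.ones(seg)
            nr = min(int(round(ramp * fs)), seg // 2)
            if nr > 0:
                edge = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
                prof[:nr] = edge
                prof[-nr:] = np.minimum(prof[-nr:], edge[::-1])
            shape[start:stop] = prof
            spans.append((b, start, stop))
        b += 1
        t0 += period
    return shape, spans


def generate_activation(task: str, duration: float, fs: float, seed: int, *,
                        labels: Sequence[str] = DEFAULT_LABELS,
                        weights: Sequence[float] | None = None,
                        bout_on: float = 2.0, bout_off: float = 2.0,
                        ramp: float = 0.3) -> np.ndarray:
    """Per-channel activation envelopes in [0, 1], shape (T, C).

    Effort bouts of ``bout_on`` seconds alternate with rest; rest samples are
    exactly zero.  Each channel's bout amplitude is its normalized task weight
    scaled by an independent per-bout recruitment jitter (uniform in
    [0.55, 1.0]), so channel envelopes share the bout schedule but are not
    proportional to one another.
    """
    w = np.asarray(weights if weights is not None else task_weights(task), dtype=float)
    if duration < bout_on + bout_off:
        raise ValueError("duration must cover at least one rest+effort bout")
    gains = w / w.max() if w.max() > 0 else w
    shape, spans = _bout_shape(duration, fs, bout_on, bout_off, ramp)
    env = np.zeros((len(shape), len(w)))
    for c, label in enumerate(labels):
        rng = _stream(seed, f"bouts:{label}")
        for b, start, stop in spans:
            # one uniform draw per scheduled bout, consumed in schedule order
            jitter = 0.55 + 0.45 * rng.random()
            env[start:stop, c] = gains[c] * jitter * shape[start:stop]
    return env


def _bandpass_noise(rng: np.random.Generator, n: int, fs: float,
                    band: tuple[float, float], order: int = 4) -> np.ndarray:
    sos = sps.butter(order, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n + int(fs)))[int(fs):]  # drop transient
    return x / x.std()


# Tonic firing rates (Hz) whose inter-spike intervals are whole samples at
# 1 kHz; physiological range for sustained isometric contraction.
_FIRING_RATES: tuple[float, ...] = (10.0, 20.0, 25.0)


def _ricker(fs: float, f_c: float) -> np.ndarray:
    """Stereotyped biphasic action-potential wavelet with spectral peak ~f_c."""
    sigma = 1.0 / (np.pi * f_c * np.sqrt(2.0))
    t = np.arange(-3 * sigma, 3 * sigma, 1.0 / fs)
    a = (t / sigma) ** 2
    return (1.0 - a) * np.exp(-a / 2.0)


def _muap_carrier(rng: np.random.Generator, n: int, fs: float, n_units: int,
                  f_range: tuple[float, float]) -> np.ndarray:
    """Unit-variance carrier: superposed periodic MUAP trains.

    Each motor unit fires tonically (regular inter-spike interval) with a
    random phase offset and a random per-unit amplitude; summed trains give a
    line spectrum at firing-rate harmonics shaped by the MUAP wavelet, so the
    power concentrates in the 20-150 Hz band.
    """
    x = np.zeros(n)
    for _ in range(n_units):
        rate = _FIRING_RATES[rng.integers(len(_FIRING_RATES))]
        period = int(round(fs / rate))
        phase = int(rng.integers(period))
        amp = 0.5 + 0.5 * rng.random()
        f_c = f_range[0] + (f_range[1] - f_range[0]) * rng.random()
        wavelet = _ricker(fs, f_c)
        train = np.zeros(n)
        train[phase::period] = amp
        x += sps.fftconvolve(train, wavelet, mode="full")[: n]
    return x / x.std()


def _saturating(u: np.ndarray) -> np.ndarray:
    """Monotone saturating activation-to-force map g: [0,1] -> [0,1].

    Mildly saturating so the input-scaling sensitivity w * u * g'(u) stays
    monotone in the planted weight w; stronger saturation would flatten the
    dominant muscle's sensitivity and break the planted importance ranking.
    """
    return np.tanh(u) / np.tanh(1.0)


def generate_recording(config: SynthConfig) -> Recording:
    """Generate one seeded Recording per the configured task and artifacts."""
    cfg = config
    n, fs = cfg.n_samples, cfg.fs
    t = np.arange(n) / fs
    env = generate_activation(cfg.task, cfg.duration, fs, cfg.seed,
                              labels=cfg.channel_labels, weights=cfg.weights,
                              bout_on=cfg.bout_on, bout_off=cfg.bout_off,
                              ramp=cfg.ramp)

    common = _muap_carrier(_stream(cfg.seed, "common-carrier"), n, fs,
                           cfg.n_motor_units, cfg.muap_center_range)
    rho = cfg.channel_corr
    nf = cfg.carrier_noise_frac
    signals = np.empty((n, cfg.n_channels))
    for c, label in enumerate(cfg.channel_labels):
        crng = _stream(cfg.seed, f"carrier:{label}")
        own = _muap_carrier(crng, n, fs, cfg.n_motor_units, cfg.muap_center_range)
        broadband = _bandpass_noise(crng, n, fs, cfg.carrier_band)
        det = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * own
        carrier = np.sqrt(1.0 - nf) * det + np.sqrt(nf) * broadband
        x = env[:, c] * carrier

        prng = _stream(cfg.seed, f"phase:{label}")
        if cfg.powerline_amplitude > 0:
            x = x + cfg.powerline_amplitude * np.sin(
                2 * np.pi * cfg.powerline_hz * t + 2 * np.pi * prng.random())
        if cfg.ecg_amplitude > 0:
            # narrowband cardiac interference: slowly amplitude-modulated tone
            lp = sps.butter(2, 1.5, btype="lowpass", fs=fs, output="sos")
            m = sps.sosfilt(lp, prng.standard_normal(n + int(fs)))[int(fs):]
            m = 1.0 + 0.5 * m / m.std()
            x = x + cfg.ecg_amplitude * np.clip(m, 0.1, None) * np.sin(
                2 * np.pi * cfg.ecg_artifact_hz * t + 2 * np.pi * prng.random())

        p_noise = x.var() / 10.0 ** (cfg.snr_db / 10.0)
        x = x + np.sqrt(p_noise) * _stream(cfg.seed, f"noise:{label}").standard_normal(n)
        signals[:, c] = x

    w = np.asarray(cfg.weights)
    force = cfg.force_scale * (_saturating(env) @ w) / w.sum()
    force = force + cfg.force_noise * cfg.force_scale * \
        _stream(cfg.seed, "force-noise").standard_normal(n)
    return Recording(signals=signals, force=force, fs=fs,
                     labels=tuple(cfg.channel_labels), truth=cfg)


def generate_task_suite(base_config: SynthConfig) -> dict[str, Recording]:
    """One Recording per task (flexion/extension/pronation/supination).

    Each task uses its planted default weight vector and a distinct seed
    derived deterministically from the base seed.
    """
    suite = {}
    for i, task in enumerate(TASKS):
        child_seed = int((base_config.seed * 1_000_003 + i + 1) % (2**31))
        cfg = replace(base_config, task=task, weight_vector=None, seed=child_seed)
        suite[task] = generate_recording(cfg)
    return suite
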
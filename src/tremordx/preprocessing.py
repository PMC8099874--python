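"""Signal conditioning and spectrotemporal representation.

The canonical chain is: downsample to 100 Hz -> demean -> sliding-window
periodogram (Hamming 100, overlap 90, NFFT 256) -> log + per-grid
standardization for the network.  A 20 s recording yields a (129, 191) grid;
frequency of bin k is k * 100/256 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .data import TremorSignal

__all__ = [
    "SpectrogramParams",
    "Spectrogram",
    "SPECTROGRAM_SHAPE",
    "downsample",
    "demean",
    "compute_spectrogram",
    "scale_for_network",
    "preprocess_signal",
    "n_frames",
]

TARGET_FS = 100.0
SPECTROGRAM_SHAPE = (129, 191)  # one-sided bins x frames for 2000 samples
_LOG_EPS = 1e-12


@dataclass(frozen=True)
class SpectrogramParams:
    window_len: int = 100
    overlap: int = 90
    nfft: int = 256
    window_shape: str = "hamming"
    scaling: str = "log_power"  # network input scaling: log_power | linear_power

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < self.window_len:
            raise ValueError("overlap must satisfy 0 <= overlap < window_len")
        if self.nfft < self.window_len:
            raise ValueError("nfft must be >= window_len")
        if self.scaling not in ("log_power", "linear_power"):
            raise ValueError(f"unknown scaling: {self.scaling}")

    @property
    def step(self) -> int:
        return self.window_len - self.overlap

    @property
    def n_bins(self) -> int:
        return self.nfft // 2 + 1


@dataclass
class Spectrogram:
    """One-sided spectrotemporal power grid (frequency x time)."""

    power: np.ndarray
    freq_step_hz: float
    time_step_s: float
    source: Optional[dict] = None

    @property
    def shape(self) -> tuple:
        return self.power.shape

    def frequencies_hz(self) -> np.ndarray:
        return np.arange(self.power.shape[0]) * self.freq_step_hz


def n_frames(n_samples: int, params: SpectrogramParams | None = None) -> int:
    params = params or SpectrogramParams()
    return (n_samples - params.window_len) // params.step + 1


def downsample(signal: TremorSignal, target_fs: float = TARGET_FS) -> TremorSignal:
    """Anti-aliased integer-factor decimation with a zero-phase FIR.

    The low-pass is a symmetric (linear-phase) Hamming FIR with cutoff at
    0.45 * target_fs, applied with reflected edges so there is no group delay.
    """
    factor = signal.fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"sampling rate {signal.fs} is not an integer multiple of {target_fs}"
        )
    factor = int(round(factor))
    if factor == 1:
        return signal.replace_samples(signal.samples.copy())

    # Hamming design: ~53 dB stopband; transition width ~3.3 * fs / numtaps.
    # Size taps so the response is down before the new Nyquist (0.5*target_fs).
    transition_hz = 0.1 * target_fs
    numtaps = int(np.ceil(3.3 * signal.fs / transition_hz)) | 1
    taps = sps.firwin(numtaps, cutoff=0.45 * target_fs, fs=signal.fs, window="hamming")
    pad = numtaps // 2
    padded = np.pad(signal.samples, pad, mode="reflect")
    filtered = sps.fftconvolve(padded, taps, mode="valid")
    return signal.replace_samples(filtered[::factor], fs=target_fs)


def demean(signal: TremorSignal) -> TremorSignal:
    """Subtract the sample mean (removes calibration/posture offsets)."""
    if signal.n_samples == 0:
        raise ValueError("cannot demean an empty signal")
    return signal.replace_samples(signal.samples - signal.samples.mean())


def compute_spectrogram(
    signal: TremorSignal, params: SpectrogramParams | None = None
) -> Spectrogram:
    """Sliding-window periodogram: per-frame |FFT|^2, no frame averaging.

    Frame j (0-based) covers samples [step*j, step*j + window_len); each frame
    is Hamming-windowed, zero-padded to nfft, and squared.  No window-power
    normalization is applied (absolute scale is irrelevant downstream).
    """
    params = params or SpectrogramParams()
    x = np.asarray(signal.samples, dtype=float)
    if x.shape[0] < params.window_len:
        raise ValueError(
            f"signal too short for spectrogram: {x.shape[0]} < {params.window_len}"
        )
    window = sps.get_window(params.window_shape, params.window_len, fftbins=False)
    frames = sliding_window_view(x, params.window_len)[:: params.step]
    spectrum = np.fft.rfft(frames * window, n=params.nfft, axis=1)
    power = np.abs(spectrum) ** 2  # (n_frames, n_bins)
    return Spectrogram(
        power=power.T.copy(),
        freq_step_hz=signal.fs / params.nfft,
        time_step_s=params.step / signal.fs,
        source={
            "patient_id": signal.patient_id,
            "group": signal.group.value,
            "visit": signal.visit,
            "hand": signal.hand.value,
            "task": signal.task.value,
            "trial": signal.trial,
            "axis": signal.axis.value,
        },
    )


def scale_for_network(spec: Spectrogram, log_power: bool = True) -> Spectrogram:
    """Log-compress (optional) and standardize one grid to zero mean/unit var.

    Zero-variance grids map to all zeros.  Deterministic; uses no population
    statistics, so it cannot leak information across train/test splits.
    """
    z = np.log10(spec.power + _LOG_EPS) if log_power else spec.power.astype(float)
    sd = z.std()
    z = np.zeros_like(z) if sd < 1e-15 else (z - z.mean()) / sd
    return replace(spec, power=z)


def preprocess_signal(
    signal: TremorSignal,
    params: SpectrogramParams | None = None,
    target_fs: float = TARGET_FS,
) -> Spectrogram:
    """Full per-signal chain: downsample -> demean -> spectrogram -> scale."""
    params = params or SpectrogramParams()
    sig = downsample(signal, target_fs) if signal.fs != target_fs else signal
    sig = demean(sig)
    spec = compute_spectrogram(sig, params)
    return scale_for_network(spec, log_power=params.scaling == "log_power")
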
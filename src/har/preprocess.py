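"""Outlier and noise removal plus PSD estimation.

The cleaning recipe is the standard wearable-sensor one: a short running
median knocks out isolated spikes, then a zero-phase third-order low-pass
Butterworth removes high-frequency acquisition noise.  The filtering is
applied forward and backward (``filtfilt``) because the pipeline is offline;
this doubles the attenuation in the stopband and leaves no group delay, so
features and labels stay aligned.

The Welch power spectral density is used to choose the low-pass cutoff by
inspection: body-motion energy lives below a few Hz, so the cutoff is placed
where the PSD has tapered off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .sensor_io import SensorStream


@dataclass
class PSDCurve:
    """One-sided Welch power spectral density, one column per channel."""

    frequencies: np.ndarray
    power: np.ndarray  # (n_freqs, n_channels)
    channels: tuple[str, ...]

    def channel(self, name: str) -> np.ndarray:
        return self.power[:, self.channels.index(name)]


def median_filter(s: SensorStream, kernel: int = 3) -> SensorStream:
    """Running median per channel with reflect-padding at the edges."""
    if kernel % 2 == 0:
        raise ValueError(f"kernel must be odd, got {kernel}")
    if kernel < 1 or kernel > s.n_samples:
        raise ValueError(f"kernel {kernel} out of range for stream of length {s.n_samples}")
    out = ndimage.median_filter(s.data, size=(kernel, 1), mode="reflect")
    return s.with_data(out)


def butterworth_lowpass(s: SensorStream, order: int = 3, cutoff_hz: float = 20.0) -> SensorStream:
    """Zero-phase (forward-backward) low-pass Butterworth per channel."""
    nyquist = s.rate_hz / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz is not below the Nyquist frequency {nyquist} Hz; "
            "resample to a higher rate first or skip the low-pass stage"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=s.rate_hz, output="sos")
    out = signal.sosfiltfilt(sos, s.data, axis=0)
    return s.with_data(out)


def butterworth_twopass_gain(f_hz: float, cutoff_hz: float, rate_hz: float, order: int = 3) -> float:
    """Analytic magnitude response of the two-pass digital Butterworth.

    The filter is designed by the bilinear transform, so its single-pass
    squared magnitude at frequency f is ``1 / (1 + (tan(pi f/fs)/tan(pi fc/fs))^(2n))``;
    forward-backward filtering applies it twice.
    """
    warped = np.tan(np.pi * f_hz / rate_hz) / np.tan(np.pi * cutoff_hz / rate_hz)
    return float(1.0 / (1.0 + warped ** (2 * order)))


def psd(s: SensorStream, method: str = "welch", nperseg: int = 256) -> PSDCurve:
    """Per-channel one-sided PSD (Welch, Hann window, 50% overlap)."""
    if method != "welch":
        raise ValueError(f"unknown PSD method {method!r}")
    if s.n_samples < nperseg:
        raise ValueError(f"stream length {s.n_samples} is shorter than nperseg {nperseg}")
    freqs, power = signal.welch(
        s.data, fs=s.rate_hz, window="hann", nperseg=nperseg, noverlap=nperseg // 2, axis=0
    )
    return PSDCurve(freqs, power, s.channels)
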
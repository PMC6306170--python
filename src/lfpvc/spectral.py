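"""State-conditioned spectral analysis: epoching, Welch spectra, spectrograms.

Epochs are 15 s by default, giving a Rayleigh frequency resolution of
1/15 ≈ 0.067 Hz (finer than 0.1 Hz).  State-averaged power spectra are
Welch estimates (5 s Hann segments, 50% overlap) computed inside each epoch
of the requested vigilance state and averaged across epochs; densities are
reported one-sided in μV²/Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import signal

from .simulate import RecordingSession

__all__ = ["EpochSet", "PowerSpectrum", "epochize", "state_spectrum", "spectrogram"]

_V_TO_UV = 1e6


@dataclass
class EpochSet:
    """Slices (start, duration in seconds) of one vigilance state."""

    state: str
    slices: List[Tuple[float, float]]

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def empty(self) -> bool:
        return not self.slices


@dataclass
class PowerSpectrum:
    """One-sided Welch power spectral density, μV²/Hz, with estimator metadata."""

    frequencies: np.ndarray
    power: np.ndarray
    state: str = ""
    mode: str = ""
    n_epochs: int = 0
    meta: Dict = field(default_factory=dict)

    def total_power(self, fmin: float = 0.0, fmax: Optional[float] = None) -> float:
        """Integrated power (μV²) over [fmin, fmax] by trapezoidal rule."""
        fmax = fmax if fmax is not None else float(self.frequencies[-1])
        sel = (self.frequencies >= fmin) & (self.frequencies <= fmax)
        return float(np.trapezoid(self.power[sel], self.frequencies[sel]))

    def peak_frequency(self, fmin: float = 0.0, fmax: Optional[float] = None) -> float:
        fmax = fmax if fmax is not None else float(self.frequencies[-1])
        sel = (self.frequencies >= fmin) & (self.frequencies <= fmax)
        return float(self.frequencies[sel][np.argmax(self.power[sel])])


def epochize(
    session: RecordingSession,
    state: str,
    epoch_length: Optional[float] = None,
) -> EpochSet:
    """Slice a session's hypnogram epochs of one state into analysis epochs.

    Each hypnogram epoch of the requested state is chopped into
    ``epoch_length``-second slices lying entirely inside it (default: the
    hypnogram's own epoch granularity).  An absent state yields an empty,
    flagged set rather than an error.
    """
    if session.hypnogram is None:
        raise ValueError("session has no hypnogram")
    slices: List[Tuple[float, float]] = []
    for e in session.hypnogram.epochs_of(state):
        length = epoch_length or e.duration
        k = int(e.duration / length + 1e-9)
        slices.extend((e.start + i * length, length) for i in range(k))
    if not slices:
        warnings.warn(f"no {state} epochs in session; returning an empty epoch set")
    return EpochSet(state, slices)


def _slice_samples(trace: np.ndarray, fs: float, start: float, duration: float) -> np.ndarray:
    i0 = int(round(start * fs))
    i1 = i0 + int(round(duration * fs))
    return trace[i0:i1]


def state_spectrum(
    session: RecordingSession,
    state: str,
    area: str = "CA1",
    mode: str = "DR",
    epoch_length: Optional[float] = None,
    segment_s: float = 5.0,
    overlap: float = 0.5,
    window: str = "hann",
) -> PowerSpectrum:
    """Welch spectrum of one area/montage-mode, averaged over state epochs."""
    epochs = epochize(session, state, epoch_length)
    if epochs.empty:
        raise ValueError(f"no {state} epochs to average")
    trace = session.in_mode(area, mode) * _V_TO_UV
    fs = session.fs
    nperseg = int(round(segment_s * fs))
    noverlap = int(round(overlap * nperseg))

    accum = None
    freqs = None
    for start, duration in epochs.slices:
        x = _slice_samples(trace, fs, start, duration)
        if len(x) < nperseg:
            raise ValueError(
                f"epoch ({duration:.3g} s) shorter than the Welch segment "
                f"({segment_s:.3g} s)"
            )
        freqs, pxx = signal.welch(
            x, fs=fs, window=window, nperseg=nperseg, noverlap=noverlap,
            detrend="constant",
        )
        accum = pxx if accum is None else accum + pxx
    power = accum / len(epochs)
    return PowerSpectrum(
        frequencies=freqs,
        power=power,
        state=state,
        mode=mode,
        n_epochs=len(epochs),
        meta={
            "area": area,
            "segment_s": segment_s,
            "overlap": overlap,
            "window": window,
            "units": "uV^2/Hz",
        },
    )


def spectrogram(
    trace: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    overlap: float = 0.9,
    normalize: bool = True,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time power map (frequencies, times, power).

    With ``normalize`` the map is scaled to unit maximum, matching the
    normalised-colour convention used for time–frequency displays.
    """
    nperseg = int(round(window_s * fs))
    if nperseg > len(trace):
        raise ValueError("spectrogram window longer than the trace")
    f, t, sxx = signal.spectrogram(
        trace, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)), detrend="constant",
    )
    if normalize and sxx.max() > 0:
        sxx = sxx / sxx.max()
    return f, t, sxx
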
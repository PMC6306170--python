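"""Detection of sporadic band-limited burst events (10–14 Hz by default).

Pipeline: zero-phase 4th-order Butterworth band-pass → analytic-signal
envelope → threshold at envelope mean + k·SD (statistics restricted to a
state mask when given) → minimum duration → merge events separated by short
gaps.  Only the band is physiologically pinned; the remaining choices are
conventional envelope-detector settings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal

__all__ = ["BurstEvent", "detect_bursts", "match_events"]


@dataclass(frozen=True)
class BurstEvent:
    """Detected band-limited event."""

    channel: str
    start: float
    end: float
    peak_amplitude: float
    center_frequency: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("event end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


def _runs(above: np.ndarray) -> List[Tuple[int, int]]:
    """[start, stop) index runs of True values."""
    padded = np.diff(np.concatenate(([0], above.astype(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts, stops))


def detect_bursts(
    trace: np.ndarray,
    fs: float,
    band: Tuple[float, float] = (10.0, 14.0),
    channel: str = "",
    threshold_sd: float = 2.0,
    boundary_sd: float = 0.5,
    min_duration: float = 0.4,
    merge_gap: float = 0.2,
    mask: Optional[np.ndarray] = None,
    threshold: Optional[float] = None,
) -> List[BurstEvent]:
    """Detect envelope-threshold events of a frequency band.

    Two-threshold (hysteresis) scheme: an event must hold the envelope above
    the detection threshold (mean + ``threshold_sd``·SD) for at least
    ``min_duration``; its boundaries are then extended outward to where the
    envelope crosses the lower boundary threshold (mean +
    ``boundary_sd``·SD), so reported onsets track the true event onset
    rather than the detection crossing.

    Parameters
    ----------
    mask : boolean ndarray, optional
        Restricts both the envelope statistics and the detection to the
        samples of one vigilance state (the containing state's epochs).
    threshold : float, optional
        Absolute envelope threshold; overrides the mean + k·SD rule (the
        boundary threshold is then ``boundary_sd / threshold_sd`` of it).
    """
    lo, hi = band
    if not (0 < lo < hi):
        raise ValueError("band must be an increasing positive pair")
    if hi >= fs / 2:
        raise ValueError(f"band upper edge {hi} Hz at or beyond Nyquist ({fs / 2} Hz)")
    trace = np.asarray(trace, dtype=float)
    if mask is not None and mask.shape != trace.shape:
        raise ValueError("mask must match the trace shape")

    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, trace)
    envelope = np.abs(signal.hilbert(filtered))

    stats_region = envelope[mask] if mask is not None else envelope
    if threshold is None:
        mu, sd = float(stats_region.mean()), float(stats_region.std())
        threshold = mu + threshold_sd * sd
        boundary = mu + boundary_sd * sd
    else:
        boundary = threshold * (boundary_sd / threshold_sd)

    above = envelope > threshold
    above_low = envelope > boundary
    if mask is not None:
        above &= mask
        above_low &= mask

    min_len = int(round(min_duration * fs))
    spans = [(a, b) for a, b in _runs(above) if b - a >= min_len]

    # hysteresis: widen each core span to its containing low-threshold run
    low_runs = _runs(above_low)
    widened: List[Tuple[int, int]] = []
    starts = np.array([a for a, _ in low_runs]) if low_runs else np.empty(0)
    for a, b in spans:
        i = int(np.searchsorted(starts, a, side="right")) - 1
        if 0 <= i < len(low_runs) and low_runs[i][1] >= b:
            widened.append(low_runs[i])
        else:
            widened.append((a, b))
    spans = sorted(set(widened))

    merged: List[Tuple[int, int]] = []
    gap_len = int(round(merge_gap * fs))
    for a, b in spans:
        if merged and a - merged[-1][1] < gap_len:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))

    events: List[BurstEvent] = []
    for a, b in merged:
        seg = filtered[a:b]
        freqs = np.fft.rfftfreq(len(seg), d=1.0 / fs)
        spec = np.abs(np.fft.rfft(seg * np.hanning(len(seg))))
        in_band = (freqs >= lo) & (freqs <= hi)
        if in_band.any():
            f_peak = float(freqs[in_band][np.argmax(spec[in_band])])
        else:
            f_peak = 0.5 * (lo + hi)
        events.append(
            BurstEvent(
                channel=channel,
                start=a / fs,
                end=b / fs,
                peak_amplitude=float(envelope[a:b].max()),
                center_frequency=f_peak,
            )
        )
    return events


def match_events(
    detected: Sequence,
    truth: Sequence,
    tolerance: float = 0.25,
) -> Tuple[float, float, int]:
    """Greedy one-to-one matching of detected events against ground truth.

    Events match when their spans overlap, or their boundaries come within
    ``tolerance`` seconds.  Accepts any objects exposing either
    ``start``/``end`` or ``onset``/``duration``.

    Returns
    -------
    (sensitivity, precision, n_matched)
    """

    def _span(ev) -> Tuple[float, float]:
        if hasattr(ev, "onset"):
            return float(ev.onset), float(ev.onset + ev.duration)
        if hasattr(ev, "start"):
            return float(ev.start), float(ev.end)
        a, b = ev
        return float(a), float(b)

    det = sorted((_span(e) for e in detected), key=lambda s: s[0])
    tru = sorted((_span(e) for e in truth), key=lambda s: s[0])
    used = np.zeros(len(det), dtype=bool)
    matched = 0
    for t0, t1 in tru:
        for i, (d0, d1) in enumerate(det):
            if used[i]:
                continue
            if d0 <= t1 + tolerance and d1 >= t0 - tolerance:
                used[i] = True
                matched += 1
                break
    sensitivity = matched / len(tru) if tru else float("nan")
    precision = matched / len(det) if det else float("nan")
    return sensitivity, precision, matched
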
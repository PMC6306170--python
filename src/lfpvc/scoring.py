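"""Rule-based vigilance-state scoring from EEG/EMG-like channels.

Per-epoch features follow the standard rodent signatures: Wake shows strong
muscle tone (EMG RMS), NREM shows large delta-band (0.5–4 Hz) power, REM
shows theta-band (6–10 Hz) dominance with muscle atonia.  The decision
rules are applied in that order:

1. EMG RMS above threshold            → Wake
2. else delta power above threshold   → NREM
3. else theta/delta ratio above thr.  → REM
4. else                               → NREM

Thresholds are derived per recording by a deterministic two-class split
(Otsu's criterion on the log feature), which stays valid when one state
holds the majority of epochs; single-epoch state islands are absorbed by
their neighbours.
"""

from __future__ import annotations

from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .simulate import Epoch, Hypnogram

__all__ = ["epoch_features", "score_states", "agreement"]

DELTA_BAND = (0.5, 4.0)
THETA_BAND = (6.0, 10.0)


def _band_power(x: np.ndarray, fs: float, band: Tuple[float, float]) -> float:
    nperseg = min(len(x), int(4 * fs))
    freqs, pxx = signal.welch(x, fs=fs, nperseg=nperseg, detrend="constant")
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.trapezoid(pxx[sel], freqs[sel]))


def epoch_features(
    eeg: np.ndarray,
    emg: np.ndarray,
    fs: float,
    epoch_length: float = 15.0,
) -> pd.DataFrame:
    """Per-epoch delta power, theta power, theta/delta ratio and EMG RMS."""
    eeg = np.asarray(eeg, dtype=float)
    emg = np.asarray(emg, dtype=float)
    if eeg.shape != emg.shape:
        raise ValueError("eeg and emg must have equal duration")
    n_per = int(round(epoch_length * fs))
    n_epochs = len(eeg) // n_per
    if n_epochs == 0:
        raise ValueError("epoch_length longer than the recording")
    rows = []
    for i in range(n_epochs):
        sl = slice(i * n_per, (i + 1) * n_per)
        delta = _band_power(eeg[sl], fs, DELTA_BAND)
        theta = _band_power(eeg[sl], fs, THETA_BAND)
        rows.append(
            {
                "start_s": i * epoch_length,
                "delta": delta,
                "theta": theta,
                "ratio": theta / max(delta, 1e-300),
                "emg_rms": float(np.sqrt(np.mean(emg[sl] ** 2))),
            }
        )
    return pd.DataFrame(rows)


def _otsu_threshold(values: np.ndarray) -> float:
    """Deterministic two-class split maximising between-class variance of the
    log feature; returns the threshold in original units."""
    v = np.sort(np.log10(np.asarray(values, dtype=float) + 1e-300))
    n = len(v)
    if n < 2 or v[0] == v[-1]:
        return float(10 ** v[-1]) * 2.0  # degenerate: everything below
    best_k, best_score = None, -np.inf
    cumsum = np.cumsum(v)
    total = cumsum[-1]
    for k in range(1, n):
        w0 = k / n
        w1 = 1.0 - w0
        mu0 = cumsum[k - 1] / k
        mu1 = (total - cumsum[k - 1]) / (n - k)
        score = w0 * w1 * (mu0 - mu1) ** 2
        if score > best_score:
            best_score, best_k = score, k
    thr_log = 0.5 * (v[best_k - 1] + v[best_k])
    return float(10 ** thr_log)


def _smooth_islands(labels: list) -> list:
    out = list(labels)
    for i in range(1, len(out) - 1):
        if out[i] != out[i - 1] and out[i - 1] == out[i + 1]:
            out[i] = out[i - 1]
    return out


def score_states(
    eeg: np.ndarray,
    emg: np.ndarray,
    fs: float,
    epoch_length: float = 15.0,
    thresholds: Optional[Dict[str, float]] = None,
    smooth: bool = True,
) -> Tuple[Hypnogram, Dict[str, float]]:
    """Score Wake/NREM/REM epochs from an EEG-like and an EMG trace.

    Returns the scored hypnogram together with the thresholds used (keys
    ``emg``, ``delta``, ``ratio``), so a scoring can be reproduced exactly.
    """
    feats = epoch_features(eeg, emg, fs, epoch_length)
    if thresholds is None:
        delta = feats["delta"].to_numpy()
        delta_thr = _otsu_threshold(delta)
        # EMG and theta/delta are trimodal across all epochs (Wake, NREM and
        # REM each have their own level); once the high-delta NREM epochs are
        # set aside both features are cleanly bimodal, so their thresholds
        # are derived on the low-delta subset
        sub = delta <= delta_thr
        if sub.sum() < 4:
            sub = np.ones(len(feats), dtype=bool)
        thresholds = {
            "emg": _otsu_threshold(feats["emg_rms"].to_numpy()[sub]),
            "delta": delta_thr,
            "ratio": _otsu_threshold(feats["ratio"].to_numpy()[sub]),
        }
    labels = []
    for row in feats.itertuples():
        if row.emg_rms > thresholds["emg"]:
            labels.append("Wake")
        elif row.delta > thresholds["delta"]:
            labels.append("NREM")
        elif row.ratio > thresholds["ratio"]:
            labels.append("REM")
        else:
            labels.append("NREM")
    if smooth and len(labels) > 2:
        labels = _smooth_islands(labels)
    hyp = Hypnogram(
        [Epoch(i * epoch_length, epoch_length, s) for i, s in enumerate(labels)]
    )
    return hyp, thresholds


def agreement(scored: Hypnogram, truth: Hypnogram) -> float:
    """Fraction of epochs on the common grid where the labels agree."""
    a = scored.labels()
    b = truth.labels()
    n = min(len(a), len(b))
    if n == 0:
        raise ValueError("empty hypnograms")
    return float(np.mean([a[i] == b[i] for i in range(n)]))
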
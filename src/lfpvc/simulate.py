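"""Synthetic multi-area LFP sessions rendered through the volume-conduction model.

The generator emulates a chronic dual-area rodent recording: an electrode
pair in dorsal hippocampus (CA1) and another in medial prefrontal cortex
(PFC), plus one distant skull reference and an EMG channel.  A hypnogram of
Wake / NREM / REM epochs drives state-conditioned current sources:

* REM — a continuous 7 Hz theta source next to the CA1 pair, and sporadic
  10–14 Hz bursts present in *both* areas with a fixed inter-areal
  conduction delay (default 35 ms, PFC lagging CA1);
* NREM — a ~1 Hz slow-oscillation source per area and per-area sleep
  spindles in the same 10–14 Hz band;
* all states — per-area pink-noise background sources and one strong
  *distal common* pink-noise source that both referential channels pick up
  through volume conduction;
* EMG — broadband noise gated by state (high in Wake, low in NREM,
  near-zero in REM atonia).

Every electrode trace is the superposition over sources of the monopole
potential I/(4πσd) times the source waveform, so the referential channels
(electrode − reference) inherit the distal contamination while the
differential channels (contact 1 − contact 2) suppress it by the
geometric factor derived in :mod:`lfpvc.forward`.  Ground truth (sources,
burst schedule, hypnogram, seed) is carried by the session object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .forward import (
    CurrentSource,
    ElectrodePair,
    Medium,
    SingularityError,
    _FOUR_PI,
)

__all__ = [
    "STATES",
    "Epoch",
    "Hypnogram",
    "build_hypnogram",
    "ElectrodeMontage",
    "default_montage",
    "BurstSpec",
    "ScheduledSource",
    "SourceEnsemble",
    "SourceParams",
    "build_sources",
    "render",
    "RecordingSession",
]

STATES = ("Wake", "NREM", "REM")

ELECTRODE_LABELS = ("CA1_e1", "CA1_e2", "PFC_e1", "PFC_e2", "REF")
CHANNEL_LABELS = ELECTRODE_LABELS + ("EMG",)


# ---------------------------------------------------------------------------
# hypnogram
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Epoch:
    start: float
    duration: float
    state: str

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("epoch duration must be positive")
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class Hypnogram:
    """Contiguous, non-overlapping sequence of labelled vigilance epochs."""

    epochs: List[Epoch]

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("hypnogram must contain at least one epoch")
        for prev, cur in zip(self.epochs, self.epochs[1:]):
            if abs(cur.start - prev.end) > 1e-9:
                raise ValueError("epochs must be contiguous and non-overlapping")

    @property
    def duration(self) -> float:
        return self.epochs[-1].end - self.epochs[0].start

    def epochs_of(self, state: str) -> List[Epoch]:
        return [e for e in self.epochs if e.state == state]

    def counts(self) -> Dict[str, int]:
        return {s: len(self.epochs_of(s)) for s in STATES}

    def state_mask(self, state: str, fs: float, n: int) -> np.ndarray:
        """Boolean per-sample mask of the given state."""
        mask = np.zeros(n, dtype=bool)
        for e in self.epochs_of(state):
            i0 = int(round(e.start * fs))
            i1 = min(int(round(e.end * fs)), n)
            mask[i0:i1] = True
        return mask

    def state_at(self, t: float) -> str:
        for e in self.epochs:
            if e.start <= t < e.end:
                return e.state
        return self.epochs[-1].state

    def labels(self) -> List[str]:
        return [e.state for e in self.epochs]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_s": [e.start for e in self.epochs],
                "duration_s": [e.duration for e in self.epochs],
                "state": [e.state for e in self.epochs],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Hypnogram":
        return cls(
            [
                Epoch(float(r.start_s), float(r.duration_s), str(r.state))
                for r in frame.itertuples()
            ]
        )


#: per-state epoch counts of the default session (sleep counts follow the
#: reference recording protocol: 195 NREM + 110 REM 15-s epochs per animal)
DEFAULT_COUNTS: Dict[str, int] = {"Wake": 40, "NREM": 195, "REM": 110}

DEFAULT_EPOCH_LENGTH = 15.0


def build_hypnogram(
    counts: Optional[Mapping[str, int]] = None,
    epoch_length: float = DEFAULT_EPOCH_LENGTH,
    seed=None,
    mean_bout_epochs: float = 5.0,
) -> Hypnogram:
    """Randomised, seed-reproducible hypnogram realising exact epoch counts.

    States are laid out in bouts (geometric bout lengths, mean
    ``mean_bout_epochs``) drawn without replacement from the requested
    per-state epoch budgets, so the requested counts are realised exactly
    while the ordering is random but reproducible.
    """
    if counts is None:
        counts = DEFAULT_COUNTS
    counts = {s: int(counts.get(s, 0)) for s in STATES}
    if any(c < 0 for c in counts.values()):
        raise ValueError("epoch counts must be non-negative")
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("all epoch counts are zero: empty session")

    rng = np.random.default_rng(seed)
    remaining = dict(counts)
    sequence: List[str] = []
    prev: Optional[str] = None
    while sum(remaining.values()) > 0:
        avail = [s for s in STATES if remaining[s] > 0 and s != prev]
        if not avail:  # only the previous state has budget left
            avail = [s for s in STATES if remaining[s] > 0]
        weights = np.array([remaining[s] for s in avail], dtype=float)
        state = avail[rng.choice(len(avail), p=weights / weights.sum())]
        bout = min(int(rng.geometric(1.0 / mean_bout_epochs)), remaining[state])
        bout = max(bout, 1)
        sequence.extend([state] * bout)
        remaining[state] -= bout
        prev = state

    epochs = [
        Epoch(i * epoch_length, epoch_length, s) for i, s in enumerate(sequence)
    ]
    return Hypnogram(epochs)


# ---------------------------------------------------------------------------
# montage
# ---------------------------------------------------------------------------

@dataclass
class ElectrodeMontage:
    """Named bipolar pairs plus the position of the common reference.

    The reference must be a genuinely cold spot: at least ``reference_factor``
    times farther from every rendered source than any pair midpoint is.
    """

    pairs: Dict[str, ElectrodePair]
    reference: np.ndarray
    reference_factor: float = 10.0

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        if self.reference.shape != (3,):
            raise ValueError("reference must be a 3-vector")

    @property
    def areas(self) -> Tuple[str, ...]:
        return tuple(self.pairs)

    def electrode_positions(self) -> Dict[str, np.ndarray]:
        out: Dict[str, np.ndarray] = {}
        for area, pair in self.pairs.items():
            p1, p2 = pair.electrode_positions
            out[f"{area}_e1"] = p1
            out[f"{area}_e2"] = p2
        out["REF"] = self.reference
        return out

    def validate_source_position(self, position: np.ndarray) -> None:
        position = np.asarray(position, dtype=float)
        d_ref = float(np.linalg.norm(self.reference - position))
        for area, pair in self.pairs.items():
            d_mid = float(np.linalg.norm(pair.midpoint - position))
            if d_ref < self.reference_factor * d_mid:
                raise ValueError(
                    f"reference is only {d_ref / max(d_mid, 1e-30):.1f}x farther "
                    f"from a source than the {area} pair midpoint "
                    f"(needs >= {self.reference_factor}x)"
                )


def default_montage(half_separation: float = 100e-6) -> ElectrodeMontage:
    """Default dual-area montage.

    CA1 and PFC pair midpoints 6.5 mm apart along x (the stereotaxic
    anteroposterior axis), pair axes along the inter-areal line, and the
    skull reference 80 mm off-axis so it is >=10x farther than any pair
    midpoint from every default source, including the distal common one.
    """
    axis = np.array([1.0, 0.0, 0.0])
    return ElectrodeMontage(
        pairs={
            "CA1": ElectrodePair(np.zeros(3), axis, half_separation),
            "PFC": ElectrodePair(np.array([6.5e-3, 0.0, 0.0]), axis, half_separation),
        },
        reference=np.array([3.25e-3, -80e-3, 0.0]),
    )


# ---------------------------------------------------------------------------
# sources
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BurstSpec:
    """Ground-truth 10–14 Hz event: onset/duration/frequency, the areas it
    appears in, and the inter-areal delay (positive = PFC later)."""

    onset: float
    duration: float
    frequency: float
    areas: Tuple[str, ...]
    delay: float = 0.0

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class ScheduledSource:
    """A current source with a role tag and a start time for its waveform."""

    role: str
    source: CurrentSource
    start: float = 0.0


@dataclass
class SourceEnsemble:
    sources: List[ScheduledSource]
    bursts: List[BurstSpec]
    fs: float
    n_samples: int
    hypnogram: Hypnogram

    def by_role(self, *roles: str) -> "SourceEnsemble":
        """Sub-ensemble keeping only the given role tags (for rendering
        source classes separately)."""
        keep = [s for s in self.sources if s.role in roles]
        return SourceEnsemble(keep, self.bursts, self.fs, self.n_samples, self.hypnogram)


@dataclass
class SourceParams:
    """Generator parameters: geometry offsets, oscillator bands, rates and
    source current amplitudes.

    Amplitudes (amperes) are calibrated so that, with the default montage,
    the CA1 referential channel carries ~10x the total power of the
    differential one during REM, with the distal common source dominating
    the referential channels — the regime the forward model predicts for a
    conventional monopolar recording.
    """

    fs: float = 1000.0

    # state-conditioned oscillators
    theta_freq: float = 7.0
    theta_amp: float = 1.9e-7
    so_band: Tuple[float, float] = (0.5, 1.5)
    so_amp: float = 6.0e-7
    burst_band: Tuple[float, float] = (10.0, 14.0)
    burst_amp: float = 2.3e-7
    burst_duration: float = 0.8
    burst_rate_rem: float = 6.0 / 60.0     # common CA1+PFC events, Hz
    spindle_rate_nrem: float = 3.0 / 60.0  # per-area events, Hz
    delay: float = 0.035                   # inter-areal delay, s (PFC lagging)

    # backgrounds
    noise_exponent: float = 1.0
    background_amp: float = 1.0e-7
    distal_amp: float = 1.2e-5
    # the aggregate of many asynchronous remote populations is spectrally
    # shallower than a single local background; a flatter exponent also puts
    # common-mode power into the burst band, which is what degrades the
    # referential channels' band SNR
    distal_exponent: float = 0.5
    # distant aggregate activity reaching the electrodes is low-pass in
    # practice; the cutoff also sets how sharply the common-mode
    # cross-correlation peaks at zero lag
    distal_lowpass: float = 30.0

    # geometry: source offsets relative to each pair midpoint (m), and the
    # absolute position of the distal common source
    local_offset: Tuple[float, float, float] = (1.5e-4, 1.5e-4, 0.0)
    burst_offset: Tuple[float, float, float] = (1.8e-4, -1.2e-4, 0.0)
    so_offset: Tuple[float, float, float] = (-2.0e-4, 2.0e-4, 0.0)
    background_offset: Tuple[float, float, float] = (2.5e-4, 3.0e-4, 0.0)
    distal_position: Tuple[float, float, float] = (3.25e-3, 7.3e-3, 0.0)

    montage: ElectrodeMontage = field(default_factory=default_montage)

    # smooth on/off ramp applied to state gates, s
    gate_ramp: float = 0.25

    def __post_init__(self) -> None:
        if self.delay >= self.burst_duration:
            raise ValueError("inter-areal delay must be shorter than the burst")
        if not (0 < self.burst_band[0] < self.burst_band[1]):
            raise ValueError("burst_band must be an increasing positive pair")


def _smooth_gate(mask: np.ndarray, fs: float, ramp: float) -> np.ndarray:
    """Turn a boolean mask into a 0..1 envelope with cosine-tapered edges."""
    gate = mask.astype(float)
    n_ramp = int(round(ramp * fs))
    if n_ramp > 1:
        win = np.hanning(2 * n_ramp + 1)
        win = win / win.sum()
        gate = signal.fftconvolve(gate, win, mode="same")
        np.clip(gate, 0.0, 1.0, out=gate)
    return gate


def _active_rms_normalise(w: np.ndarray, mask: np.ndarray) -> np.ndarray:
    active = w[mask] if mask.any() else w
    rms = float(np.sqrt(np.mean(active**2)))
    return w / rms if rms > 0 else w


def pink_noise(n: int, rng: np.random.Generator, exponent: float = 1.0,
               f_low: float = 0.5, fs: float = 1000.0,
               f_high: Optional[float] = None) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise, flattened below ``f_low`` to keep the
    variance finite and optionally rolled off (4th-order) above ``f_high``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    pinned = np.maximum(freqs[nonzero], f_low)
    scale[nonzero] = pinned ** (-exponent / 2.0)
    scale[0] = 0.0
    if f_high is not None:
        scale /= np.sqrt(1.0 + (freqs / f_high) ** 8)
    out = np.fft.irfft(spec * scale, n=n)
    return out / np.sqrt(np.mean(out**2))


def _poisson_schedule(
    epochs: Sequence[Epoch],
    rate: float,
    duration: float,
    margin: float,
    rng: np.random.Generator,
    min_gap: float,
) -> List[float]:
    """Poisson event onsets within epochs, each event fitting entirely inside
    its epoch; overlapping events (onset gap < min_gap) are dropped."""
    onsets: List[float] = []
    for e in epochs:
        room = e.duration - duration - margin
        if room <= 0:
            continue
        k = rng.poisson(rate * e.duration)
        if k == 0:
            continue
        local = np.sort(rng.uniform(0.0, room, size=k))
        kept: List[float] = []
        for o in local:
            if not kept or o - kept[-1] >= min_gap:
                kept.append(float(o))
        onsets.extend(e.start + o for o in kept)
    return onsets


def _burst_waveform(duration: float, freq: float, fs: float) -> np.ndarray:
    """Hann-windowed sinusoid with unit peak envelope."""
    n = max(int(round(duration * fs)), 2)
    t = np.arange(n) / fs
    return np.hanning(n) * np.sin(2.0 * np.pi * freq * t)


def build_sources(
    hypnogram: Hypnogram,
    params: Optional[SourceParams] = None,
    seed=None,
) -> SourceEnsemble:
    """State-conditioned source schedule for a hypnogram.

    REM epochs receive the continuous CA1 theta source and Poisson-scheduled
    10–14 Hz bursts common to CA1 and PFC (the PFC copy delayed by
    ``params.delay``); NREM epochs receive per-area slow-oscillation sources
    and independent per-area spindles; pink backgrounds and the distal
    common source are always on.
    """
    params = params or SourceParams()
    fs = params.fs
    nyq_needed = 2.0 * max(params.theta_freq, params.burst_band[1], params.so_band[1])
    if fs <= nyq_needed:
        raise ValueError("sampling rate must exceed twice the highest oscillator frequency")

    n = int(round(hypnogram.duration * fs))
    t = np.arange(n) / fs
    rng = np.random.default_rng(seed)
    streams = rng.spawn(8)
    (theta_rng, so_rng, bg_rng, distal_rng,
     burst_rng, spindle_rng, _r6, _r7) = streams

    montage = params.montage
    pairs = montage.pairs
    sources: List[ScheduledSource] = []
    bursts: List[BurstSpec] = []

    rem_mask = hypnogram.state_mask("REM", fs, n)
    nrem_mask = hypnogram.state_mask("NREM", fs, n)

    def _pos(area: str, offset) -> np.ndarray:
        return pairs[area].midpoint + np.asarray(offset, dtype=float)

    # --- continuous CA1 theta during REM -----------------------------------
    if rem_mask.any():
        phase = theta_rng.uniform(0.0, 2.0 * np.pi)
        w = np.sin(2.0 * np.pi * params.theta_freq * t + phase)
        w *= _smooth_gate(rem_mask, fs, params.gate_ramp)
        w = _active_rms_normalise(w, rem_mask)
        sources.append(
            ScheduledSource(
                "local_CA1",
                CurrentSource(_pos("CA1", params.local_offset), params.theta_amp, w),
            )
        )

    # --- per-area slow oscillation during NREM ------------------------------
    if nrem_mask.any():
        sos = signal.butter(2, params.so_band, btype="bandpass", fs=fs, output="sos")
        for area in pairs:
            w = signal.sosfiltfilt(sos, so_rng.standard_normal(n))
            w *= _smooth_gate(nrem_mask, fs, params.gate_ramp)
            w = _active_rms_normalise(w, nrem_mask)
            sources.append(
                ScheduledSource(
                    f"local_{area}",
                    CurrentSource(_pos(area, params.so_offset), params.so_amp, w),
                )
            )

    # --- always-on backgrounds and the distal common source -----------------
    for area in pairs:
        w = pink_noise(n, bg_rng, params.noise_exponent, fs=fs)
        sources.append(
            ScheduledSource(
                "background",
                CurrentSource(_pos(area, params.background_offset),
                              params.background_amp, w),
            )
        )
    w = pink_noise(n, distal_rng, params.distal_exponent, fs=fs,
                   f_high=params.distal_lowpass)
    sources.append(
        ScheduledSource(
            "distal_common",
            CurrentSource(np.asarray(params.distal_position, dtype=float),
                          params.distal_amp, w),
        )
    )

    # --- sporadic common bursts during REM ----------------------------------
    lo, hi = params.burst_band
    for onset in _poisson_schedule(
        hypnogram.epochs_of("REM"), params.burst_rate_rem, params.burst_duration,
        params.delay, burst_rng, min_gap=2.0 * params.burst_duration,
    ):
        freq = float(burst_rng.uniform(lo, hi))
        wave = _burst_waveform(params.burst_duration, freq, fs)
        bursts.append(
            BurstSpec(onset, params.burst_duration, freq, ("CA1", "PFC"), params.delay)
        )
        sources.append(
            ScheduledSource(
                "burst_CA1",
                CurrentSource(_pos("CA1", params.burst_offset), params.burst_amp, wave),
                start=onset,
            )
        )
        sources.append(
            ScheduledSource(
                "burst_PFC",
                CurrentSource(_pos("PFC", params.burst_offset), params.burst_amp, wave),
                start=onset + params.delay,
            )
        )

    # --- per-area NREM spindles (same band, no inter-areal locking) ---------
    for area in pairs:
        for onset in _poisson_schedule(
            hypnogram.epochs_of("NREM"), params.spindle_rate_nrem,
            params.burst_duration, 0.0, spindle_rng,
            min_gap=2.0 * params.burst_duration,
        ):
            freq = float(spindle_rng.uniform(lo, hi))
            wave = _burst_waveform(params.burst_duration, freq, fs)
            bursts.append(BurstSpec(onset, params.burst_duration, freq, (area,), 0.0))
            sources.append(
                ScheduledSource(
                    f"burst_{area}",
                    CurrentSource(_pos(area, params.burst_offset), params.burst_amp, wave),
                    start=onset,
                )
            )

    return SourceEnsemble(sources, bursts, fs, n, hypnogram)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class RecordingSession:
    """Multichannel rendered session with montage metadata and ground truth.

    ``data`` rows follow ``labels``; raw electrode potentials are stored and
    the montage channels are derived on demand:
    RR(area) = area_e1 − REF, DR(area) = area_e1 − area_e2.
    """

    data: np.ndarray
    labels: Tuple[str, ...]
    fs: float
    montage: ElectrodeMontage
    hypnogram: Optional[Hypnogram] = None
    bursts: Optional[List[BurstSpec]] = None
    seed: Optional[int] = None

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.labels.index(label)]
        except ValueError as exc:
            raise KeyError(f"no channel {label!r}") from exc

    def rr(self, area: str) -> np.ndarray:
        """Referential (monopolar) trace of an area: first contact − REF."""
        return self.channel(f"{area}_e1") - self.channel("REF")

    def dr(self, area: str) -> np.ndarray:
        """Differential (bipolar) trace of an area: contact 1 − contact 2."""
        return self.channel(f"{area}_e1") - self.channel(f"{area}_e2")

    def in_mode(self, area: str, mode: str) -> np.ndarray:
        if mode == "RR":
            return self.rr(area)
        if mode == "DR":
            return self.dr(area)
        raise ValueError("mode must be 'RR' or 'DR'")

    def common_bursts(self) -> List[BurstSpec]:
        """Ground-truth events present in more than one area."""
        if not self.bursts:
            return []
        return [b for b in self.bursts if len(b.areas) > 1]


#: EMG broadband-noise gain per vigilance state (atonia in REM)
DEFAULT_EMG_STATE_GAIN = {"Wake": 1.0, "NREM": 0.1, "REM": 0.02}


def render(
    ensemble: SourceEnsemble,
    montage: Optional[ElectrodeMontage] = None,
    medium: Optional[Medium] = None,
    seed=None,
    emg_amp: float = 100e-6,
    emg_state_gain: Optional[Mapping[str, float]] = None,
    sensor_noise: float = 0.0,
) -> RecordingSession:
    """Render electrode traces: superposition of monopole potentials.

    Each electrode trace is Σ_sources I/(4πσ d) · waveform(t − start).  The
    EMG channel is state-gated broadband noise (not forward-modelled), and
    ``sensor_noise`` (volts RMS) optionally adds white amplifier noise to
    every channel (default off, keeping rendering exactly linear in the
    source amplitudes).
    """
    montage = montage or default_montage()
    medium = medium or Medium()
    n = ensemble.n_samples
    fs = ensemble.fs
    positions = montage.electrode_positions()

    for sched in ensemble.sources:
        montage.validate_source_position(sched.source.position)
        for pos in positions.values():
            if np.linalg.norm(pos - sched.source.position) == 0.0:
                raise SingularityError(f"source coincides with an electrode ({sched.role})")

    data = np.zeros((len(CHANNEL_LABELS), n))
    sigma = medium.conductivity
    for sched in ensemble.sources:
        src = sched.source
        if src.waveform is None:
            raise ValueError(f"scheduled source {sched.role!r} has no waveform")
        i0 = int(round(sched.start * fs))
        i1 = min(i0 + len(src.waveform), n)
        if i1 <= i0:
            continue
        segment = src.waveform[: i1 - i0]
        for ch, label in enumerate(ELECTRODE_LABELS):
            d = float(np.linalg.norm(positions[label] - src.position))
            data[ch, i0:i1] += src.amplitude / (_FOUR_PI * sigma * d) * segment

    rng = np.random.default_rng(seed)
    emg_rng, sensor_rng = rng.spawn(2)

    gains = dict(DEFAULT_EMG_STATE_GAIN)
    if emg_state_gain:
        gains.update(emg_state_gain)
    if emg_amp > 0:
        envelope = np.zeros(n)
        for state, g in gains.items():
            envelope += g * _smooth_gate(
                ensemble.hypnogram.state_mask(state, fs, n), fs, 0.25
            )
        data[-1] = emg_amp * envelope * emg_rng.standard_normal(n)

    if sensor_noise > 0:
        data += sensor_noise * sensor_rng.standard_normal(data.shape)

    seed_out = seed if isinstance(seed, (int, np.integer)) else None
    return RecordingSession(
        data=data,
        labels=CHANNEL_LABELS,
        fs=fs,
        montage=montage,
        hypnogram=ensemble.hypnogram,
        bursts=list(ensemble.bursts),
        seed=seed_out,
    )


def simulate_session(
    counts: Optional[Mapping[str, int]] = None,
    params: Optional[SourceParams] = None,
    epoch_length: float = DEFAULT_EPOCH_LENGTH,
    seed=None,
    **render_kwargs,
) -> RecordingSession:
    """Convenience one-call generator: hypnogram → sources → rendered session.

    The single seed is expanded deterministically into independent child
    seeds for the hypnogram, the source schedule and the rendering noise.
    """
    ss = np.random.SeedSequence(seed)
    s_hyp, s_src, s_render = ss.spawn(3)
    params = params or SourceParams()
    hyp = build_hypnogram(counts, epoch_length=epoch_length, seed=s_hyp)
    ensemble = build_sources(hyp, params, seed=s_src)
    session = render(ensemble, params.montage, seed=s_render, **render_kwargs)
    if isinstance(seed, (int, np.integer)):
        session.seed = int(seed)
    return session
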
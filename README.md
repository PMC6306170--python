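# lfpvc — referential vs differential LFP recordings under volume conduction

Local field potentials (LFPs) are usually recorded *referentially* (RR): one
electrode in the structure of interest against a distant skull reference.
Because the extracellular medium conducts, that montage also picks up every
distant source between electrode and reference — *volume conduction* — which
inflates coherence between brain areas and hides genuine propagation delays.
A *differential* (bipolar, DR) montage — two contacts separated by 2ε in the
same structure — suppresses distant sources geometrically and isolates the
local signal.

`lfpvc` is a Python library for quantifying that difference. It provides:

* **Forward model** (`lfpvc.forward`) — ohmic point-source physics. A source
  *I* in a homogeneous medium of conductivity σ creates
  *V(r) = I / 4πσr*. A bipolar pair at distance *r* and angle α sees the
  exact law-of-cosines difference, with the far-field limit
  ΔV_dist = 2Iε·cos α / 4πσr² and the near-field limit
  ΔV_loc = I(cos α/2 − sin α/2) / 4πσε·sin α. The ratio of their
  angle-independent parts is the pair's common-mode rejection ratio,
  **Γ = (√2/4)(r/ε)²**, and the montage signal-to-noise ratios for a local
  source at ε against a distal one at *r* are SNR_RR = r/ε and
  SNR_DR = Γ, with per-axis gain γ = (√2/4)(r/ε).
* **Synthetic recordings** (`lfpvc.simulate`, `lfpvc.io`) — hypnogram-driven
  dual-area (CA1, PFC) sessions rendered through the forward model: REM
  theta, NREM slow oscillations and spindles, sporadic 10–14 Hz bursts
  common to both areas with a 35 ms inter-areal delay, pink backgrounds, a
  strong distal common source and a state-gated EMG channel; EDF output
  with CSV hypnogram and JSON ground truth.
* **Analyses** — state-averaged Welch spectra and spectrograms
  (`lfpvc.spectral`), envelope-threshold burst detection (`lfpvc.events`),
  magnitude-squared and imaginary coherence, burst-triggered coherence,
  event-wise cross-correlation lag distributions and a coherence-vs-noise
  simulation with hyperbolic-secant fit (`lfpvc.connectivity`), rule-based
  sleep scoring (`lfpvc.scoring`), and an end-to-end seeded pipeline
  (`lfpvc.workflow`, CLI `lfpvc run`).

## Worked example

```python
from lfpvc import detect_bursts, lag_distribution, match_events, simulate_session

session = simulate_session({"Wake": 4, "NREM": 10, "REM": 12}, seed=3)
mask = session.hypnogram.state_mask("REM", session.fs, session.n_samples)
events = detect_bursts(session.dr("CA1"), session.fs, mask=mask)
for mode in ("DR", "RR"):
    d = lag_distribution(session, events, mode=mode)
    print(mode, round(d.median * 1e3, 1), "ms, IQR", round(d.iqr * 1e3, 1), "ms")
```

prints

```
DR 35.0 ms, IQR 0.0 ms
RR 0.0 ms, IQR 39.0 ms
```

— the differential montage recovers the injected 35 ms CA1→PFC conduction
delay event by event, while the referential montage, dominated by the
zero-lag volume-conducted common source, yields a broad lag distribution
centred on zero. `examples/` contains one short script per capability
(montage theory table, simulate-and-score, RR-vs-DR spectra, burst lags,
coherence-vs-noise), each printing the numbers it computes and what they
mean.

A montage theory table is one call away:

```bash
lfpvc theory -r 6
```

which reports Γ = 12.7, SNR_RR = 6, SNR_DR = 12.7, per-axis gain 2.12 and a
3-D global SNR advantage of 2³ = 8 for a distal source at r = 6ε.

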
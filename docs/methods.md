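# Methods

## Forward model

The extracellular medium is treated as linear, homogeneous, isotropic and
purely ohmic (conductivity σ, default 0.3 S/m — a typical gray-matter
value; every reported ratio is σ-independent). A point source of current
*I* then produces the quasi-static monopole potential V(r) = I/4πσr, and
all electrode traces are superpositions of such monopoles. Capacitive or
inhomogeneous media, finite electrode geometry and current-source-density
inversion are out of scope; the ohmic approximation is adequate below
~100 Hz and beyond ~100 μm source–electrode distances, which is the regime
every analysis here operates in.

A bipolar pair is described by its midpoint, unit axis and half-separation
ε (default 100 μm, within the practical 50–200 μm range for twisted-wire
pairs). For a source at midpoint distance *r* and axis angle α, three
difference laws are exposed: the exact law-of-cosines form, the distal
limit 2Iε·cos α/4πσr² (r ≫ ε), and the local limit
I(cos(α/2) − sin(α/2))/4πσε·sin α obtained by collapsing r onto ε. The
local form is verified in the tests to be algebraically identical to the
exact law evaluated at r = ε. The common-mode rejection ratio
Γ = (√2/4)(r/ε)² is the ratio of the angle-independent parts of the local
and distal laws; the montage SNRs follow as SNR_RR = r/ε, SNR_DR = Γ,
γ = SNR_DR/SNR_RR = (√2/4)(r/ε). The 3-D global advantage rounds the
per-axis gain to the nearest integer before cubing (γ ≈ 2.12 → 2 → 8),
which is the convention the per-axis product argument uses. The γ = 1
crossover is solved numerically (Brent) rather than assigned; it sits at
r/ε = 2√2 ≈ 2.83.

Accuracy of the distal limit: expanding the exact difference to second
order gives a relative error of (ε/r)²·|3/2 − (5/2)cos²α| + O((ε/r)⁴).
The error is therefore *not* uniformly ≈ (ε/r)²: it vanishes near
cos²α = 3/5, equals (ε/r)² on axis, and rises to 1.5(ε/r)² as α → π/2.
The property tests assert the correct bound 1.55(ε/r)² on a dense grid
against direct coordinate evaluation.

## Synthetic sessions

The generator emulates a chronic dual-area rat recording (dorsal CA1 and
medial PFC), not any particular animal: its purpose is a ground-truthed
testbed in which the montage effects predicted by the forward model can be
measured.

**Hypnogram.** Wake/NREM/REM epochs of 15 s (chosen so a single epoch
supports a 1/15 Hz ≈ 0.067 Hz spectral resolution), laid out in bouts with
geometric length (mean 5 epochs) and exact per-state counts. The default
session has 195 NREM and 110 REM epochs — the per-animal epoch budget of
the reference recording protocol — plus 40 Wake epochs so the scorer's EMG
rule has something to find.

**Geometry.** Pair midpoints 6.5 mm apart along x (the stereotaxic AP
separation of CA1 and PFC implants), pair axes along the inter-areal line
(the pair axis is the montage's principal detection axis). The skull
reference sits 80 mm off-axis: the montage enforces that the reference is
≥10× farther from every source than any pair midpoint is, and with the
distal common source a few millimetres from both areas and the strict
reading of that rule (checked against *both* midpoints), 10 mm — a
realistic cerebellar screw — cannot satisfy it. The package prefers the
invariant (it is what makes the reference electrically "cold") over
anatomical realism of the synthetic geometry.

**Sources.** REM: a continuous 7 Hz theta source 212 μm from the CA1 pair,
and Poisson-scheduled (6/min) 0.8 s Hann-windowed bursts with per-event
carrier uniform in 10–14 Hz, present at both areas with the PFC copy
delayed 35 ms (the delay the analyses are asked to recover; positive =
PFC later). NREM: a 0.5–1.5 Hz band-noise slow-oscillation source per
area and independent per-area spindles in the same band (3/min). Always
on: per-area pink (1/f) backgrounds and one strong distal common source.
The EMG channel is state-gated broadband noise (gains 1 / 0.1 / 0.02 for
Wake/NREM/REM — REM atonia); it is a recorded muscle signal, not a
forward-modelled source. Rendering is exactly linear in the source
amplitudes; optional sensor noise is off by default.

**Distal common source.** Its waveform is 1/f^0.5 noise low-passed at
30 Hz. Both choices are deliberate: the aggregate of many asynchronous
remote populations is spectrally shallower than a single local background,
the shallow exponent puts common-mode power into the 10–14 Hz band (which
is what degrades the referential channels' band SNR and masks the burst
delay there), and the 30 Hz cutoff gives the common-mode cross-correlation
a smooth, finite-width peak at zero lag, so the referential lag
distribution is genuinely fuzzy rather than an artificial delta at zero.

**Amplitude calibration.** The source currents (theta 190 nA at 212 μm,
bursts 230 nA at 216 μm, slow oscillation 600 nA, backgrounds 100 nA at
390 μm, distal 12 μA at ~8 mm) were calibrated once, jointly, to the
qualitative structure the montage physics predicts and the package must
reproduce: CA1 REM total power ≈10× larger referentially than
differentially; the distal common source dominating the referential
channels (so RR event lags cluster broadly around zero) while contributing
negligibly to the differential ones (so DR event lags recover the 35 ms
delay with per-event peak correlations ≈0.65); bursts detectable at
envelope SNR well above threshold; and state signatures separable enough
for rule-based scoring. They were then frozen; tests run against these
defaults.

**What the generator does not emulate:** movement artifacts (the analyses
target sleep precisely to avoid them), electrode impedance and amplifier
characteristics, non-stationary oscillation frequencies, travelling-wave
phase gradients within an area, and inter-animal variability. Passing
tests therefore demonstrate that the estimators recover known structure
through the volume-conduction physics — not that they are robust to
everything real recordings contain.

## Estimators

**Spectra.** Welch, 5 s Hann segments with 50% overlap inside each 15 s
state epoch, averaged across epochs; one-sided densities in μV²/Hz.
Spectrograms use 1 s Hann windows with 90% overlap and unit-maximum
normalisation.

**Burst detection.** Zero-phase 4th-order Butterworth band-pass (10–14 Hz
by default; the band is the physiologically pinned part), analytic-signal
envelope, detection threshold mean + 2 SD of the envelope with statistics
restricted to the containing vigilance state, minimum duration 0.4 s, and
merging of events separated by <0.2 s. Event boundaries use a hysteresis
scheme: once a core detection exists, its edges extend outward to the
mean + 0.5 SD crossing, so reported onsets track the true burst onset
(±0.1 s at moderate SNR) instead of the detection crossing, which lags
systematically.

**Coherence.** Magnitude-squared coherence is the segment-averaged
cross-spectrum magnitude squared over the product of averaged
auto-spectra; imaginary coherence reports |Im| of the normalised
coherency and is blind to zero-lag (conduction-driven) coupling.
Session-level estimates pool Welch sub-segments across all epochs of one
state. Burst-triggered coherence uses one Hann-tapered window per event
(events padded to ≥1 s) and averages over events only. A single segment is
refused (the estimate is identically 1).

**Lags.** `xcorr_peak` returns the global normalised cross-correlation
peak; by default the lag maximising |r| (so an anti-correlated pair
reports its negative extremum), with a `peak="max"` option returning the
maximum-correlation lag. The lag pipeline uses `peak="max"`: for
narrow-band packets the |r| criterion is ambiguous between the true peak
and the anti-phase peak half a carrier period away (≈ 36–50 ms for
10–14 Hz), and the maximum-correlation convention — the one under which an
individual event pair shows its peak *positive* correlation at the
propagation delay — removes that ambiguity. Event windows are Hann-tapered
(matching the burst-triggered coherence windows). A `circular` option
computes FFT (circular) correlation, under which an integer-sample
circular shift is recovered with correlation exactly 1; linear correlation
necessarily loses the non-overlapping edge. The lag PDF is a Gaussian KDE
with Silverman bandwidth (empirical histogram fallback for degenerate
samples); the CDF is the empirical step function and the median the
sample median. Fewer than 10 events flags the result low-confidence.

**Coherence vs noise.** The canonical configuration places a unit sine on
bin 50 of 400-sample rectangular segments and adds Gaussian white noise of
standard deviation *n*. The expected coherence at the sine bin is
1/(1 + 4n²/N): exactly 0.5 at n = 10 (per-bin SNR 1) and 0.2 at n = 20.
The default of 10⁴ disjoint segments was fixed from a variance analysis of
the estimator — at 500 segments the standard error at the half-coherence
point is ≈0.033, too coarse for the ±0.02 band the operating point is
quoted at; at 10⁴ it is ≈0.007. `fit_sech` least-squares fits
C(n) = sech(a·n); on the default curve a ≈ 0.125, i.e. sech reaches 0.5
near n = 10.5.

**Scoring.** Per-epoch features: delta power (0.5–4 Hz), theta power
(6–10 Hz), theta/delta ratio, EMG RMS. Rules in order: Wake if EMG RMS
above threshold, else NREM if delta above threshold, else REM if
theta/delta above threshold, else NREM; single-epoch islands are absorbed
by their neighbours. Thresholds are derived per recording by a
deterministic Otsu split of the log feature rather than median ± MAD:
with NREM holding the majority of epochs the delta median lies *inside*
the NREM cluster, and a median-based threshold mislabels the majority
state wholesale. Because EMG and theta/delta are trimodal across all
epochs, their splits are computed on the low-delta subset, where both are
cleanly bimodal. Scoring a recording that genuinely contains a single
state requires explicit thresholds — no data-driven split can find a
boundary in a one-cluster feature.

## Numerical and I/O choices

Sampling rate defaults to 1 kHz (all analysed rhythms are <100 Hz; the
rate is configurable). Session files are plain EDF — one-second records,
16-bit samples, per-channel symmetric physical range with 5% headroom,
scaling computed from the header-rounded range so writing is the exact
inverse of the reader's affine map (round trip is exact to half a digital
step ≈ range/65535). The EDF writer/reader pair is implemented in
`lfpvc._edf`; the test suite cross-checks it against mne's independent EDF
parser. Hypnograms travel as CSV (start_s, duration_s, state) and ground
truth (burst schedule, montage geometry, seed) as JSON. The pipeline
expands one global seed into per-stage child seeds via numpy
`SeedSequence.spawn`, so a stored config plus seed reproduces every output
byte for byte; reports are JSON with sorted keys.

Default problem sizes: the shared test session uses 32 epochs (480 s), the
parameter-recovery checks run one full default session (345 epochs,
~86 min, ~130 burst events), and the canonical coherence curve uses 6
noise levels × 4·10⁶ samples. These sizes keep the whole suite at roughly
a minute while leaving every estimate's sampling error well inside the
asserted tolerances.

## Known limitations

* The forward model is a monopole superposition in an infinite medium; no
  boundary effects (skull, surfaces) and no dipolar source structure.
* The burst detector is an envelope thresholder; it is not a spindle
  classifier and its duration estimates depend on the boundary threshold.
* The sech description of the coherence–noise curve is an empirical fit;
  the flat-noise model itself predicts C = 1/(1 + 4n²/N), which a sech
  tracks only approximately (residual RMS ≈ 0.03 on the default curve).
* Rule-based scoring is validated only on the generator's well-separated
  states; real rodent scoring needs artifact handling and transition
  states it does not model.
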
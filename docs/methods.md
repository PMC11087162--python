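# Methods

This note documents the models, algorithms and design choices behind
`gatelat`: what the synthetic session generator emulates, how each analysis
stage works, which parameters matter, and what the validation does and does
not demonstrate.

## Signal model and simulator

A gating QA session is modeled as three synchronized analog channels
sampled at a common rate (default 10 kHz):

* **motion** — the surrogate's vertical position in mm. The clean waveform
  is `x(t) = (A/2)(1 + cos(2πt/T))` with peak-to-peak amplitude `A`
  (5–20 mm) and period `T` (3–5 s); peaks sit at integer multiples of `T`.
  The time axis is padded by half a period at both ends so every analyzed
  peak is interior to the recording. "Amplitude" is taken as peak-to-peak
  surrogate displacement throughout.
* **trigger** — the gating system's beam-permission line, two states
  (0 V / 12 V) joined by linear ramps of configurable rise time (default
  0.2 ms). Ramps rather than ideal steps ensure the threshold-crossing
  interpolation in the edge detector is actually exercised.
* **beam** — the beam detector's envelope, a ~100 mV step with the same
  ramp treatment.

Per cycle `k` (peak at `kT`), the gate opens/closes at the 40%/60% phase
times exactly by construction (peak = phase 0%/100%, so the window is
centered on the trough of the symmetric waveform). The trigger switches
ON/OFF a per-cycle gating-system latency after gate open/close, and the
beam follows each trigger edge by a per-cycle treatment-system latency.
Latencies are drawn independently per event from a normal distribution
truncated at zero — only means and SDs of the real system are known, and a
negative hardware latency is unphysical. Camera frame quantization of the
optical tracking system is not modeled separately; its jitter is part of
the end-to-end gating-system latency distribution being emulated.

The construction identity `T_beam-on − T_gate-open = rpm_on + cyc_on`
(and the OFF analogue) holds exactly, which is what makes parameter
recovery a meaningful end-to-end test.

### Noise model and defaults

* motion: white Gaussian sensor noise (default SD 0.15 mm), a mains
  interference sinusoid (50 Hz, default amplitude 0.1 mm), and sparse
  single-sample spikes (Poisson rate 0.5/s, amplitude 5× the noise SD,
  random sign) that motivate the median filter;
* trigger/beam: white Gaussian noise, defaults 0.05 V and 2 mV (~1/50 of
  each step level — small relative to the 12 V and 100 mV swings, as on
  real DAQ channels, but enough to exercise the hysteresis logic).

Default injected latency distributions are the pooled reference statistics
(gating system 104.20 ± 13.64 / 113.60 ± 14.98 ms ON/OFF; cyclotron
108.29 ± 0.85 / 1.20 ± 0.04 ms); `gatelat.presets` carries the full
11-scenario reference table and can inject each scenario's own published
row. All randomness flows from a single `numpy` generator seeded by
`ScenarioConfig.seed`, with a fixed draw order, so sessions are
bit-reproducible.

What the simulator does **not** emulate: irregular patient-like breathing
(no drift, no amplitude/period variability within a session), baseline
wander, sensor nonlinearity, trigger chatter at the gate boundary, or any
beam pulse microstructure (the beam channel is a two-state envelope).
Passing recovery tests therefore demonstrates the correctness of the
analysis chain under the stated QA conditions — sinusoidal phantom motion —
not robustness to free-breathing traces.

## Analysis pipeline

### 1. Motion denoising

A second-order IIR notch (default 50 Hz, Q = 30; both configurable, since
neither is dictated by the method) is applied forward and backward
(`filtfilt`, even/reflect padding). Zero-phase operation is essential: a
causal notch at these settings has group delay of order milliseconds in the
breathing band, which would bias every gating-system latency directly.
A centered moving median (default 11 samples = 1.1 ms at 10 kHz, reflect
padding) then removes impulsive spikes without moving edges or peaks. Only
the motion channel is filtered; trigger and beam are analyzed raw.

### 2. Peak localization and expected gate times

A threshold at `min + 0.9 × (max − min)` of the motion trace isolates one
region per breathing peak. Implementation details that matter in noise:

* runs touching either recording boundary are discarded (their peak may be
  clipped);
* noise chatter near the threshold fragments each true region into one
  long run plus many few-sample fragments. Fragmented runs separated by
  less than 10% of the *sample-weighted* median run length (the length of
  the run containing the median above-threshold sample) are merged. An
  unweighted median would be dominated by the numerous tiny fragments
  (~5 samples) and merge nothing; the weighted median tracks the true
  region width (~0.6 s) regardless of how many fragments noise creates.
* the peak-to-peak range is global over the recording by default;
  `refine_per_cycle=True` re-thresholds each region against the local
  min/max within ±0.75 median peak spacings, for drifting baselines.

Each region is least-squares fitted with a polynomial (default order 2;
order 4 also tested — for a symmetric cosine cap both localize the vertex
identically). The peak time is the argmax of the fitted polynomial on the
closed region interval, found from the derivative roots; a maximum on the
region boundary raises an error since the region then does not bracket a
peak. Peak times are invariant under gain/offset changes of the channel.

Consecutive fitted peaks `p_i < p_{i+1}` give the per-cycle period (the
nominal scenario period is never used — it is unknown for real
recordings), and the expected gate times `p_i + 0.4·period` /
`p_i + 0.6·period`, referenced to the preceding peak. Periods outside a
plausibility band (default 1–10 s) flag the cycle but do not drop it.

### 3. Edge timestamping

The trigger and beam channels are binarized with Schmitt-style hysteresis:
thresholds at 20% and 80% of the dynamic range between the 5th and 95th
percentiles of the channel (percentiles rather than min/max for robustness
to outliers; `(0, 100)` restores literal min/max). The state becomes HIGH
at the 80% threshold and LOW at the 20% threshold, so noise between the
thresholds cannot toggle it. Timestamps are placed at the *start* of each
transition — the interpolated 20% crossing of the ascent for rising edges,
the interpolated 80% crossing of the descent for falling edges — i.e. the
earliest detectable departure from the previous state. With equal rise and
fall ramps this convention biases each timestamp by 20% of the rise time
(40 µs at the 0.2 ms default), and the bias cancels entirely in the
treatment-system latencies (both terms shift equally). Transitions whose
HIGH or LOW dwell is shorter than a debounce window (default 5 ms — no
physical trigger or beam event is that short in this system) are discarded
pairwise, so directions strictly alternate.

### 4. Pairing and latency computation

Each cycle claims the first trigger rising edge in the closed window
`[gate_open − 0.25·period, gate_open + 0.5·period]`, its following falling
edge, and the first beam rising/falling edge within 1 s after the
corresponding trigger edge. A trigger edge claimed twice raises an
ambiguity error; cycles missing any member are reported incomplete and
excluded from statistics (with the count carried in the provenance record).
The six latencies are then simple subtractions in ms; the totals are
computed as component sums, never re-measured, so per-cycle additivity is
bit-exact. Negative gating-system latencies (predictive triggering) are
reported with a warning, never clamped — they must be visible in QA.

## Reporting

Scenario summaries use the arithmetic mean and the sample (n−1) standard
deviation over complete cycles; at n = 30 the n vs n−1 choice moves the SD
by ~2%. Scenario total means are derived from component means (exact
additivity). The grand Mean row is the *unweighted* mean of scenario means
(each motion pattern counts equally; a cycle-weighted pooled mean is
available as an option) and, for the SD, the standard deviation of the
pooled per-cycle population reconstructed from each scenario's (n, mean,
SD); the unweighted mean of scenario SDs is available as the alternative.
Display rounding is half-away-from-zero to 2 decimals; CSV output keeps 4.

A caveat on reproducing published summary tables from their printed rows:
rounding the rows first can shift a recomputed mean by 0.01 ms relative to
a mean computed from unrounded per-cycle data (e.g. a printed component
pair summing to 212.49 against a printed total mean of 212.50), and for
some columns the printed pooled mean differs in the last digit from the
unweighted mean of the printed column. These are second-decimal artifacts
of row rounding, not disagreements about the statistics.

## Numerical choices

* Times are stored in seconds internally; milliseconds appear only at the
  reporting boundary. Recording files serialize times with 6 decimals
  (exact on the 0.1 ms grid of a 10 kHz recording) and channel values with
  6 decimals, so file round-trips are exact to 0.5 µunit.
* Polynomial fits recentre time on the region midpoint for conditioning.
* Threshold crossings are linearly interpolated between samples; all
  sub-sample effects are far below the millisecond scale of the latencies.
* Degenerate inputs fail loudly with typed exceptions (flat motion,
  missing excursions, low SNR channels, infeasible scenario geometry).

## Validation scales

The test suite validates parameter recovery at the reference protocol's
own scale — all 11 scenarios (amplitudes 5–20 mm × periods 3–5 s, minus
the 20 mm / 3 s combination, which exceeds the phantom stage's speed
rating), 30 cycles each, 10 kHz — both noiseless (recovered means within
0.5 ms of injected; observed ≤ 0.05 ms, the residual being the 40 µs
edge-convention bias) and under the default noise model (within 3 ms;
observed ≤ 0.3 ms). Peak localization on a noisy session stays within
3 ms of ground truth (observed ~1 ms maximum). Unit tests run at 2 kHz
where sub-sample precision is not the point.

## Known limitations

* Sinusoidal QA traces only: no phase model for irregular breathing, no
  Hilbert/phase-unwrapping machinery.
* The gating window is phase-defined; displacement-gating is not modeled.
* Edge detection assumes two-state channels with a dominant dwell in each
  state per cycle; it is not a general pulse-train analyzer.
* The simulator's noise is stationary and white (plus mains interference);
  real position sensors can show drift and 1/f components that the median
  + notch chain does not specifically target.
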
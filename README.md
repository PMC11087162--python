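# gatelat

Decomposed beam-delivery latency analysis for respiratory-gated
radiotherapy QA.

## The problem

In gated particle therapy, the beam must switch on and off as a breathing
surrogate enters and leaves a preset gating window. Neither the respiratory
gating system (which watches the surrogate and raises a beam-permission
trigger line) nor the treatment system (which actually starts and stops the
beam) responds instantaneously, and the two delays add. AAPM TG-142/TG-198
recommend keeping total gating latency below 100 ms for photon therapy;
commissioning a gated proton system therefore requires measuring these
delays — and, to know *where* to optimize, measuring each system's
contribution separately.

The measurement principle is a synchronized three-channel recording
(nominally 10 kHz): surrogate position from a position sensor (mm), the
gating system's two-state 0/12 V trigger line, and a photodiode that sees
the beam as a ~100 mV step. From these, six per-cycle latencies are
computed:

```
τ_RPM-on    = T_trigger-on  − T_phase-40%        (gating system, beam ON)
τ_RPM-off   = T_trigger-off − T_phase-60%        (gating system, beam OFF)
τ_CYC-on    = T_beam-on     − T_trigger-on       (treatment system, beam ON)
τ_CYC-off   = T_beam-off    − T_trigger-off      (treatment system, beam OFF)
τ_total-on  = τ_RPM-on  + τ_CYC-on  = T_beam-on  − T_phase-40%
τ_total-off = τ_RPM-off + τ_CYC-off = T_beam-off − T_phase-60%
```

where `T_phase-40%` / `T_phase-60%` are the expected gate open/close times
(40% and 60% phase of each motion cycle, referenced to the fitted motion
peak = phase 0%), and the trigger/beam transition times come from
hysteresis edge detection at 20%/80% of each channel's dynamic range.

`gatelat` implements this analysis pipeline — mains-notch + moving-median
denoising, polynomial peak fitting, edge timestamping, per-cycle latency
decomposition, and a summary-table report — together with a synthetic
session generator that emulates the hardware platform with exactly known
injected latencies, so the whole chain can be validated by parameter
recovery.

## Worked example

Simulate a 30-cycle session (15 mm peak-to-peak, 3 s period, 10 kHz,
default noise model and latency distributions), analyze it, and check the
recovery against the generator's ground truth:

```sh
gatelat simulate --amplitude 15 --period 3 --cycles 30 --seed 7 \
    --out demo.csv --truth demo_truth.json
gatelat analyze demo.csv --out demo_latencies.csv
gatelat validate demo.csv demo_truth.json
```

```
tau_rpm_on: mean error -0.048 ms, max |error| 0.816 ms
tau_rpm_off: mean error -0.050 ms, max |error| 0.738 ms
tau_cyc_on: mean error -0.006 ms, max |error| 0.020 ms
tau_cyc_off: mean error -0.001 ms, max |error| 0.022 ms
OK: all mean recovery errors within 3.0 ms
```

The analysis recovered every injected latency component with a mean error
below 0.1 ms. `gatelat report demo_latencies.csv` then prints the QA
summary table (mean ± sample SD over the 30 cycles, ms):

```
Amplitude (mm)  Period (s)  n     tau_RPM-on (ms)     tau_RPM-off (ms)    tau_CYC-on (ms)     tau_CYC-off (ms)    tau_total-on (ms)   tau_total-off (ms)
15              3           30    103.87 ± 18.26      111.43 ± 14.30      108.59 ± 0.92       1.20 ± 0.05         212.46 ± 18.30      112.62 ± 14.32
Mean                        30    103.87 ± 18.26      111.43 ± 14.30      108.59 ± 0.92       1.20 ± 0.05         212.46 ± 18.30      112.62 ± 14.32
```

Read: in this session the gating system contributed ~104 ms and the
cyclotron ~109 ms to the beam-ON delay (total ~212 ms), while the beam-OFF
delay (~113 ms) is dominated by the gating system — the cyclotron dumps the
beam in about a millisecond. The wide SDs on the RPM columns reflect the
injected cycle-to-cycle spread; the cyclotron delays are nearly
deterministic.

The same objects are available as a library:

```python
from gatelat import ScenarioConfig, simulate_session, recover_from_session

rec, truth = simulate_session(ScenarioConfig(amplitude=15, period=3, seed=7))
latencies, provenance = recover_from_session(rec)
```

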
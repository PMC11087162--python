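"""Synthetic three-channel gating sessions with known ground truth.

This module emulates the measurement platform used for gated-beam latency
QA: a phantom stage performing vertical sinusoidal motion, an optical
respiratory-gating system that raises a 12 V trigger line some ~100 ms after
the surrogate enters the 40%-60% phase gating window, and a cyclotron whose
beam (seen as a ~100 mV photodiode step) follows the trigger with its own
ON/OFF delays.  Because every injected latency is drawn explicitly, the
generator provides exact per-cycle ground truth against which the analysis
pipeline can be validated.

Conventions
-----------
* ``amplitude`` is the peak-to-peak displacement of the surrogate (mm).
* Phase 0%/100% is the motion *peak*; gate phases are fractions of the
  cycle elapsed since the preceding peak, so the default 40%-60% window is
  centered on the trough.
* Noiseless motion peaks fall at integer multiples of the period; the time
  axis is padded by half a period at both ends so every analyzed peak is
  interior to the recording.
* Latencies are drawn per event from a normal distribution truncated at
  zero (a negative hardware latency is unphysical).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .errors import ConfigurationError, InfeasibleScenarioError
from .recording import Recording

__all__ = [
    "ScenarioConfig",
    "CycleTruth",
    "GroundTruth",
    "time_axis",
    "simulate_motion",
    "simulate_session",
]


@dataclass
class ScenarioConfig:
    """Parameters of one simulated gating scenario.

    Latency means/sds are in milliseconds; the defaults are the pooled
    ON/OFF latency statistics measured on an RPM-gated cyclotron system
    (gating system ~104/114 ms, cyclotron ~108/1.2 ms).
    """

    amplitude: float            # peak-to-peak motion, mm
    period: float               # breathing period, s
    n_cycles: int = 30
    sampling_rate: float = 10_000.0
    gate_open_phase: float = 0.40
    gate_close_phase: float = 0.60
    # gating-system (trigger) latencies, ms
    rpm_on_latency_mean: float = 104.20
    rpm_on_latency_sd: float = 13.64
    rpm_off_latency_mean: float = 113.60
    rpm_off_latency_sd: float = 14.98
    # treatment-system (beam) latencies, ms
    cyc_on_latency_mean: float = 108.29
    cyc_on_latency_sd: float = 0.85
    cyc_off_latency_mean: float = 1.20
    cyc_off_latency_sd: float = 0.04
    # channel shapes
    trigger_high_level: float = 12.0    # V
    trigger_rise_time: float = 0.2      # ms
    beam_step_level: float = 0.100      # V
    beam_rise_time: float = 0.2         # ms
    # noise model
    noise_motion_sd: float = 0.15       # mm
    powerline_freq: float = 50.0        # Hz
    powerline_amplitude: float = 0.1    # mm
    spike_rate: float = 0.5             # single-sample outliers per second
    noise_trigger_sd: float = 0.05      # V
    noise_beam_sd: float = 0.002        # V
    seed: int = 0

    def validate(self) -> None:
        if not self.amplitude > 0:
            raise ConfigurationError("amplitude: must be > 0 mm")
        if not self.period > 0:
            raise ConfigurationError("period: must be > 0 s")
        if self.n_cycles < 1:
            raise ConfigurationError("n_cycles: must be >= 1")
        if self.sampling_rate < 1000:
            raise ConfigurationError("sampling_rate: must be >= 1000 Hz")
        if not (0 <= self.gate_open_phase < self.gate_close_phase <= 1):
            raise ConfigurationError(
                "gate_open_phase/gate_close_phase: need 0 <= open < close <= 1"
            )
        for name in (
            "rpm_on_latency_mean", "rpm_off_latency_mean",
            "cyc_on_latency_mean", "cyc_off_latency_mean",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name}: latency means must be >= 0")
        for name in (
            "rpm_on_latency_sd", "rpm_off_latency_sd",
            "cyc_on_latency_sd", "cyc_off_latency_sd",
            "noise_motion_sd", "noise_trigger_sd", "noise_beam_sd",
            "powerline_amplitude", "spike_rate",
            "trigger_rise_time", "beam_rise_time",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name}: must be >= 0")

    def without_noise(self) -> "ScenarioConfig":
        """Copy of this config with all stochastic terms switched off."""
        return dataclasses.replace(
            self,
            rpm_on_latency_sd=0.0, rpm_off_latency_sd=0.0,
            cyc_on_latency_sd=0.0, cyc_off_latency_sd=0.0,
            noise_motion_sd=0.0, powerline_amplitude=0.0,
            spike_rate=0.0, noise_trigger_sd=0.0, noise_beam_sd=0.0,
        )


@dataclass
class CycleTruth:
    """Exact event times for one simulated gating cycle (times s, latencies ms)."""

    index: int
    true_peak_time: float
    true_gate_open_time: float      # peak + gate_open_phase * period
    true_gate_close_time: float     # peak + gate_close_phase * period
    injected_rpm_on: float
    injected_rpm_off: float
    injected_cyc_on: float
    injected_cyc_off: float
    true_trigger_on_time: float
    true_trigger_off_time: float
    true_beam_on_time: float
    true_beam_off_time: float


@dataclass
class GroundTruth:
    """Per-cycle truth for a whole simulated session."""

    cycles: list
    config: Optional[ScenarioConfig] = None

    def __len__(self) -> int:
        return len(self.cycles)


def time_axis(config: ScenarioConfig) -> np.ndarray:
    """Sample times for the scenario: ``[-period/2, n_cycles*period + period/2]``.

    Noiseless peaks then sit at t = 0, period, ..., n_cycles*period, all of
    them at least half a period away from either end of the recording.
    """
    total = (config.n_cycles + 1) * config.period
    n = int(round(total * config.sampling_rate)) + 1
    return np.arange(n) / config.sampling_rate - config.period / 2.0


def simulate_motion(config: ScenarioConfig, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Surrogate position trace in mm for the scenario.

    The clean waveform is ``(A/2) * (1 + cos(2*pi*t/T))`` (peak-to-peak
    amplitude A, peaks at multiples of T); Gaussian sensor noise, a mains
    interference sinusoid, and sparse single-sample spikes (amplitude five
    times the noise sd, Poisson-placed) are superimposed.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t = time_axis(config)
    motion = (config.amplitude / 2.0) * (1.0 + np.cos(2.0 * np.pi * t / config.period))
    if config.powerline_amplitude > 0:
        motion = motion + config.powerline_amplitude * np.sin(
            2.0 * np.pi * config.powerline_freq * t
        )
    if config.noise_motion_sd > 0:
        motion = motion + rng.normal(0.0, config.noise_motion_sd, t.size)
        if config.spike_rate > 0:
            duration = t[-1] - t[0]
            n_spikes = rng.poisson(config.spike_rate * duration)
            if n_spikes > 0:
                idx = rng.integers(0, t.size, size=n_spikes)
                sign = rng.choice([-1.0, 1.0], size=n_spikes)
                motion[idx] += 5.0 * config.noise_motion_sd * sign
    return motion


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    """n draws from Normal(mean, sd) truncated at zero; degenerate at sd=0."""
    if sd == 0.0:
        return np.full(n, float(mean))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def _add_pulse(
    time: np.ndarray,
    out: np.ndarray,
    t_on: float,
    t_off: float,
    rise_s: float,
    level: float,
) -> None:
    """Add one trapezoidal pulse (linear rise/fall of width rise_s) in place."""
    if rise_s > 0:
        i0 = np.searchsorted(time, t_on)
        i1 = np.searchsorted(time, t_on + rise_s)
        out[i0:i1] += level * (time[i0:i1] - t_on) / rise_s
        j0 = np.searchsorted(time, t_off)
        j1 = np.searchsorted(time, t_off + rise_s)
        out[i1:j0] += level
        out[j0:j1] += level * (1.0 - (time[j0:j1] - t_off) / rise_s)
    else:
        i0 = np.searchsorted(time, t_on)
        j0 = np.searchsorted(time, t_off)
        out[i0:j0] += level


def simulate_session(config: ScenarioConfig) -> tuple[Recording, GroundTruth]:
    """Generate a full three-channel session plus its exact ground truth.

    Per cycle k (noiseless peak at ``k * period``):

    * gate opens/closes at the 40%/60% phase times (exact by construction),
    * the trigger line ramps 0 -> 12 V starting ``injected_rpm_on`` ms after
      gate-open and back to 0 V ``injected_rpm_off`` ms after gate-close,
    * the beam channel steps to ``beam_step_level`` a further
      ``injected_cyc_on`` / ``injected_cyc_off`` ms after each trigger edge.

    The construction identity ``true_beam_on - true_gate_open =
    injected_rpm_on + injected_cyc_on`` therefore holds exactly.
    """
    config.validate()
    T = config.period
    gate_len = (config.gate_close_phase - config.gate_open_phase) * T
    min_gate = (config.trigger_rise_time + config.beam_rise_time) / 1000.0 + 2.0 / config.sampling_rate
    if gate_len <= min_gate:
        raise InfeasibleScenarioError(
            f"gate interval {gate_len * 1000:.3f} ms shorter than rise times + 2 samples"
        )

    rng = np.random.default_rng(config.seed)
    time = time_axis(config)
    # Draw order is fixed (motion noise, then per-event latencies, then
    # channel noise) so identical configs and seeds are bit-reproducible.
    motion = simulate_motion(config, rng)

    n = config.n_cycles
    rpm_on = _truncated_normal(rng, config.rpm_on_latency_mean, config.rpm_on_latency_sd, n)
    rpm_off = _truncated_normal(rng, config.rpm_off_latency_mean, config.rpm_off_latency_sd, n)
    cyc_on = _truncated_normal(rng, config.cyc_on_latency_mean, config.cyc_on_latency_sd, n)
    cyc_off = _truncated_normal(rng, config.cyc_off_latency_mean, config.cyc_off_latency_sd, n)

    peak_t = np.arange(n) * T
    gate_open = peak_t + config.gate_open_phase * T
    gate_close = peak_t + config.gate_close_phase * T
    trig_on = gate_open + rpm_on / 1000.0
    trig_off = gate_close + rpm_off / 1000.0
    beam_on = trig_on + cyc_on / 1000.0
    beam_off = trig_off + cyc_off / 1000.0

    rise_trig = config.trigger_rise_time / 1000.0
    rise_beam = config.beam_rise_time / 1000.0
    if np.any(trig_off - trig_on <= rise_trig) or np.any(beam_off - beam_on <= rise_beam):
        raise InfeasibleScenarioError(
            "drawn latencies leave no open trigger/beam interval in some cycle"
        )
    if np.any(trig_on[1:] <= trig_off[:-1] + rise_trig):
        raise InfeasibleScenarioError("trigger pulses of consecutive cycles overlap")

    trigger = np.zeros_like(time)
    beam = np.zeros_like(time)
    for k in range(n):
        _add_pulse(time, trigger, trig_on[k], trig_off[k], rise_trig, config.trigger_high_level)
        _add_pulse(time, beam, beam_on[k], beam_off[k], rise_beam, config.beam_step_level)
    if config.noise_trigger_sd > 0:
        trigger = trigger + rng.normal(0.0, config.noise_trigger_sd, time.size)
    if config.noise_beam_sd > 0:
        beam = beam + rng.normal(0.0, config.noise_beam_sd, time.size)

    recording = Recording(
        sampling_rate=config.sampling_rate,
        time=time,
        motion=motion,
        trigger=trigger,
        beam=beam,
        metadata={
            "amplitude_mm": config.amplitude,
            "period_s": config.period,
            "n_cycles": config.n_cycles,
            "seed": config.seed,
        },
    )
    cycles = [
        CycleTruth(
            index=k,
            true_peak_time=float(peak_t[k]),
            true_gate_open_time=float(gate_open[k]),
            true_gate_close_time=float(gate_close[k]),
            injected_rpm_on=float(rpm_on[k]),
            injected_rpm_off=float(rpm_off[k]),
            injected_cyc_on=float(cyc_on[k]),
            injected_cyc_off=float(cyc_off[k]),
            true_trigger_on_time=float(trig_on[k]),
            true_trigger_off_time=float(trig_off[k]),
            true_beam_on_time=float(beam_on[k]),
            true_beam_off_time=float(beam_off[k]),
        )
        for k in range(n)
    ]
    return recording, GroundTruth(cycles=cycles, config=config)
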
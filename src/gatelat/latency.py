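"""Per-cycle latency decomposition.

Six latencies are derived from each paired gating cycle:

* gating-system (RPM) latencies — trigger edge minus expected gate time:
  ``tau_rpm_on  = T_trigger_on  - T_gate_open``,
  ``tau_rpm_off = T_trigger_off - T_gate_close``;
* treatment-system (cyclotron) latencies — beam edge minus trigger edge:
  ``tau_cyc_on  = T_beam_on  - T_trigger_on``,
  ``tau_cyc_off = T_beam_off - T_trigger_off``;
* totals — the sums ``tau_total_on = tau_rpm_on + tau_cyc_on`` and
  ``tau_total_off = tau_rpm_off + tau_cyc_off`` (algebraically identical to
  beam edge minus gate time; computing them as sums makes the additivity
  exact by construction).

All timestamps are kept in seconds internally; latencies are reported in
milliseconds, the conventional unit for gating QA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .config import AnalysisConfig
from .edges import MatchedCycle, detect_edges, pair_gate_events
from .errors import GatelatError, PipelineError
from .phases import locate_gating_cycles
from .preprocess import preprocess_motion
from .recording import Recording

__all__ = ["CycleLatency", "compute_latencies", "recover_from_session"]

log = logging.getLogger(__name__)


@dataclass
class CycleLatency:
    """The six latency values (ms) for one gating cycle."""

    cycle_index: int
    tau_rpm_on: float
    tau_rpm_off: float
    tau_cyc_on: float
    tau_cyc_off: float
    tau_total_on: float
    tau_total_off: float
    complete: bool = True


def compute_latencies(matches: Sequence[MatchedCycle]) -> list[CycleLatency]:
    """Six subtractions per paired cycle, seconds -> milliseconds.

    Incomplete cycles (a missing trigger or beam edge) yield a NaN row with
    ``complete=False`` and a logged reason; downstream statistics use only
    complete rows but report the discarded count.  Negative gating-system
    latencies (trigger before the expected gate time, i.e. predictive
    triggering) are reported as-is with a warning, never clamped.
    """
    out: list[CycleLatency] = []
    for m in matches:
        if not m.complete:
            log.warning("cycle %d incomplete, missing %s; skipped", m.index, m.missing())
            nan = math.nan
            out.append(CycleLatency(m.index, nan, nan, nan, nan, nan, nan, complete=False))
            continue
        rpm_on = (m.trigger_on - m.cycle.gate_open_time) * 1000.0
        rpm_off = (m.trigger_off - m.cycle.gate_close_time) * 1000.0
        cyc_on = (m.beam_on - m.trigger_on) * 1000.0
        cyc_off = (m.beam_off - m.trigger_off) * 1000.0
        if rpm_on < 0 or rpm_off < 0:
            log.warning(
                "cycle %d: negative gating-system latency (early trigger): "
                "on=%.3f ms off=%.3f ms", m.index, rpm_on, rpm_off,
            )
        out.append(
            CycleLatency(
                cycle_index=m.index,
                tau_rpm_on=rpm_on,
                tau_rpm_off=rpm_off,
                tau_cyc_on=cyc_on,
                tau_cyc_off=cyc_off,
                tau_total_on=rpm_on + cyc_on,
                tau_total_off=rpm_off + cyc_off,
            )
        )
    return out


def recover_from_session(
    recording: Recording,
    config: Optional[AnalysisConfig] = None,
) -> tuple[list[CycleLatency], dict]:
    """Full pipeline: preprocess -> phases -> edges -> latencies.

    Returns the per-cycle latencies plus a provenance record (effective
    configuration hash, thresholds, cycle/edge counts, discarded cycles).
    Stage failures are re-raised as :class:`PipelineError` with the stage
    name prefixed.
    """
    config = config or AnalysisConfig()
    config.validate()
    fs = recording.sampling_rate

    try:
        motion = preprocess_motion(recording.motion, fs, config.filter)
    except GatelatError as exc:
        raise PipelineError(f"preprocess: {exc}") from exc

    try:
        cycles = locate_gating_cycles(
            motion,
            fs,
            time=recording.time,
            threshold_fraction=config.peak_threshold,
            order=config.fit_order,
            gate_open_phase=config.gate_open_phase,
            gate_close_phase=config.gate_close_phase,
            period_band=tuple(config.period_band),
            refine_per_cycle=config.refine_per_cycle,
        )
    except GatelatError as exc:
        raise PipelineError(f"phases: {exc}") from exc

    try:
        trig = detect_edges(
            recording.trigger, fs, channel="trigger",
            low_fraction=config.edge_low_fraction,
            high_fraction=config.edge_high_fraction,
            time=recording.time, debounce_ms=config.debounce_ms,
        )
        beam = detect_edges(
            recording.beam, fs, channel="beam",
            low_fraction=config.edge_low_fraction,
            high_fraction=config.edge_high_fraction,
            time=recording.time, debounce_ms=config.debounce_ms,
        )
        matches = pair_gate_events(cycles, trig, beam, config.beam_search_window_s)
    except GatelatError as exc:
        raise PipelineError(f"edges: {exc}") from exc

    latencies = compute_latencies(matches)
    n_complete = sum(1 for lat in latencies if lat.complete)
    provenance = {
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "sampling_rate_hz": fs,
        "n_cycles": len(cycles),
        "n_complete": n_complete,
        "n_discarded": len(cycles) - n_complete,
        "n_trigger_edges": len(trig),
        "n_beam_edges": len(beam),
    }
    return latencies, provenance
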
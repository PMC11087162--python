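"""Timestamped state transitions on the trigger and beam channels.

Both logic channels are two-state signals (0/12 V trigger, ~0/100 mV beam
envelope).  State is determined with Schmitt-style hysteresis at 20% / 80%
of the channel's dynamic range: the channel becomes HIGH when it reaches
the 80% threshold and LOW when it drops to the 20% threshold, so noise
between the thresholds can never toggle the state.  The reported event
timestamps sit at the *start* of each transition — a rising edge is stamped
at the interpolated 20% crossing of the ascent that reached HIGH, a falling
edge at the interpolated 80% crossing of the descent that reached LOW —
i.e. the earliest detectable departure from the previous state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import AmbiguityError, ConfigurationError, LowSNRError, NoEdgesError
from .phases import GatingCycle

__all__ = ["EdgeEvent", "MatchedCycle", "detect_edges", "pair_gate_events"]


@dataclass
class EdgeEvent:
    """One state transition on a logic channel."""

    channel: str       # "trigger" or "beam"
    direction: str     # "rising" or "falling"
    timestamp: float   # s, linearly interpolated threshold crossing
    threshold_level: float  # V, the threshold whose crossing is stamped


@dataclass
class MatchedCycle:
    """Per-cycle association of gate times with trigger and beam edges."""

    index: int
    cycle: GatingCycle
    trigger_on: Optional[float] = None
    trigger_off: Optional[float] = None
    beam_on: Optional[float] = None
    beam_off: Optional[float] = None

    @property
    def complete(self) -> bool:
        return None not in (self.trigger_on, self.trigger_off, self.beam_on, self.beam_off)

    def missing(self) -> tuple[str, ...]:
        return tuple(
            name
            for name in ("trigger_on", "trigger_off", "beam_on", "beam_off")
            if getattr(self, name) is None
        )


def _noise_estimate(x: np.ndarray) -> float:
    # robust sigma from first differences; flat segments dominate the median
    d = np.abs(np.diff(x))
    return 1.4826 * float(np.median(d)) / np.sqrt(2.0)


def _interp_crossing(time, x, j, i, level, upward: bool) -> float:
    """Interpolated time of the last crossing of `level` in [j, i]."""
    seg = x[j:i + 1]
    if upward:
        below = np.flatnonzero(seg[:-1] < level)
    else:
        below = np.flatnonzero(seg[:-1] > level)
    if below.size == 0:
        return float(time[j])
    k = j + int(below[-1])
    x0, x1 = x[k], x[k + 1]
    if x1 == x0:
        return float(time[k])
    frac = (level - x0) / (x1 - x0)
    return float(time[k] + frac * (time[k + 1] - time[k]))


def detect_edges(
    signal: np.ndarray,
    sampling_rate: float,
    channel: str = "trigger",
    low_fraction: float = 0.2,
    high_fraction: float = 0.8,
    time: Optional[np.ndarray] = None,
    debounce_ms: float = 5.0,
    percentile_span: tuple[float, float] = (5.0, 95.0),
    snr_floor: float = 10.0,
) -> list[EdgeEvent]:
    """Extract alternating rising/falling events from a two-state channel.

    The baseline and top levels are the 5th/95th percentiles of the signal
    (robust to spikes; pass ``percentile_span=(0, 100)`` for literal
    min/max).  Events whose HIGH or LOW dwell is shorter than
    ``debounce_ms`` are discarded pairwise, so single-sample glitches
    produce no events and directions strictly alternate.
    """
    x = np.asarray(signal, dtype=float)
    if time is None:
        time = np.arange(x.size) / sampling_rate
    if not 0 < low_fraction < high_fraction < 1:
        raise ConfigurationError("edge fractions: need 0 < low < high < 1")

    baseline = float(np.percentile(x, percentile_span[0]))
    top = float(np.percentile(x, percentile_span[1]))
    span = top - baseline
    if span <= 0:
        raise NoEdgesError(f"{channel}: channel has no dynamic range")
    if snr_floor > 0:
        noise = _noise_estimate(x)
        if noise > 0 and span < snr_floor * noise:
            raise LowSNRError(
                f"{channel}: dynamic range {span:.4g} V below {snr_floor}x noise "
                f"estimate {noise:.4g} V"
            )
    low = baseline + low_fraction * span
    high = baseline + high_fraction * span

    # hysteresis state machine, vectorized: only samples outside the
    # (low, high) band can change the state
    above = x >= high
    below = x <= low
    idx = np.flatnonzero(above | below)
    if idx.size == 0 or not np.any(above):
        raise NoEdgesError(f"{channel}: no excursion reaches the high threshold")
    state = above[idx]  # True = HIGH at that decisive sample
    flips = np.flatnonzero(state[1:] != state[:-1]) + 1

    events: list[EdgeEvent] = []
    for f in flips:
        i = int(idx[f])        # first sample in the new state
        j = int(idx[f - 1])    # last decisive sample of the old state
        if state[f]:           # LOW -> HIGH: stamp the 20% crossing of the ascent
            ts = _interp_crossing(time, x, j, i, low, upward=True)
            events.append(EdgeEvent(channel, "rising", ts, low))
        else:                  # HIGH -> LOW: stamp the 80% crossing of the descent
            ts = _interp_crossing(time, x, j, i, high, upward=False)
            events.append(EdgeEvent(channel, "falling", ts, high))

    # debounce: drop adjacent event pairs closer than the minimum dwell
    min_dwell = debounce_ms / 1000.0
    changed = True
    while changed and len(events) >= 2:
        changed = False
        for k in range(len(events) - 1):
            if events[k + 1].timestamp - events[k].timestamp < min_dwell:
                del events[k:k + 2]
                changed = True
                break
    return events


def _first_at_or_after(times: np.ndarray, t: float, limit: float) -> Optional[float]:
    k = int(np.searchsorted(times, t))
    if k < times.size and times[k] - t <= limit:
        return float(times[k])
    return None


def pair_gate_events(
    cycles: Sequence[GatingCycle],
    trigger_edges: Sequence[EdgeEvent],
    beam_edges: Sequence[EdgeEvent],
    beam_search_window: float = 1.0,
) -> list[MatchedCycle]:
    """Associate each gating cycle with its trigger and beam edge pair.

    For each cycle the first trigger rising edge inside the closed window
    ``[gate_open - 0.25 * period, gate_open + 0.5 * period]`` is taken, then
    its paired falling edge, then the first beam rising/falling edge within
    ``beam_search_window`` seconds after the corresponding trigger edge.
    Cycles missing any member are returned incomplete (callers report the
    count); a trigger edge claimed by two cycles raises AmbiguityError.
    """
    trig_rise = np.array([e.timestamp for e in trigger_edges if e.direction == "rising"])
    trig_fall = np.array([e.timestamp for e in trigger_edges if e.direction == "falling"])
    beam_rise = np.array([e.timestamp for e in beam_edges if e.direction == "rising"])
    beam_fall = np.array([e.timestamp for e in beam_edges if e.direction == "falling"])

    matches: list[MatchedCycle] = []
    claimed: dict[float, int] = {}
    ambiguous: list[int] = []
    for i, cyc in enumerate(cycles):
        m = MatchedCycle(index=i, cycle=cyc)
        w0 = cyc.gate_open_time - 0.25 * cyc.cycle_period
        w1 = cyc.gate_open_time + 0.5 * cyc.cycle_period
        in_window = trig_rise[(trig_rise >= w0) & (trig_rise <= w1)]
        if in_window.size:
            t_on = float(in_window[0])
            if t_on in claimed:
                ambiguous.extend([claimed[t_on], i])
            claimed[t_on] = i
            m.trigger_on = t_on
            k = int(np.searchsorted(trig_fall, t_on))
            if k < trig_fall.size:
                m.trigger_off = float(trig_fall[k])
            if m.trigger_on is not None:
                m.beam_on = _first_at_or_after(beam_rise, m.trigger_on, beam_search_window)
            if m.trigger_off is not None:
                m.beam_off = _first_at_or_after(beam_fall, m.trigger_off, beam_search_window)
        matches.append(m)
    if ambiguous:
        raise AmbiguityError(
            f"trigger edges claimed by multiple cycles: indices {sorted(set(ambiguous))}"
        )
    return matches
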
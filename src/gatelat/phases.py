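"""Motion-peak localization and expected gate ON/OFF times.

The gating phase reference follows the standard surrogate-trace procedure:
samples above 90% of the peak-to-peak motion amplitude isolate one region
per breathing peak; each region is least-squares fitted with a low-order
polynomial and the fitted maximum is the peak time.  Consecutive fitted
peaks define the per-cycle period, and the expected gate open/close times
are the 40%/60% phase positions referenced to the preceding peak (peak =
phase 0%/100%, so the default window is centered on the trough).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    DegeneratePeakError,
    FitError,
    InsufficientCyclesError,
    NoCyclesError,
)

__all__ = [
    "PeakRegion",
    "GatingCycle",
    "find_peak_regions",
    "fit_peak",
    "expected_gate_times",
    "locate_gating_cycles",
]


@dataclass
class PeakRegion:
    """Half-open sample-index range [start, end) covering one motion peak."""

    start_index: int
    end_index: int
    threshold_used: float  # mm

    def __len__(self) -> int:
        return self.end_index - self.start_index


@dataclass
class GatingCycle:
    """One breathing cycle with its expected gate ON/OFF times (seconds)."""

    peak_time: float
    cycle_period: float
    gate_open_time: float
    gate_close_time: float
    fit_order: Optional[int] = None
    fit_rmse: Optional[float] = None
    plausible: bool = True


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True in a boolean array."""
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def find_peak_regions(
    motion: np.ndarray,
    sampling_rate: float,
    threshold_fraction: float = 0.9,
    merge_gap_fraction: float = 0.1,
    refine_per_cycle: bool = False,
) -> list[PeakRegion]:
    """Isolate one above-threshold region per motion peak.

    The threshold is ``min + threshold_fraction * (max - min)`` over the
    whole trace.  Runs touching either recording boundary are discarded
    (their peak may be clipped); runs separated by less than
    ``merge_gap_fraction`` of the median run length are merged (noise can
    split the flat top of a peak).  With ``refine_per_cycle=True`` each
    region is re-thresholded against the local min/max within +-0.75 median
    peak spacings, which tolerates a drifting baseline.
    """
    motion = np.asarray(motion, dtype=float)
    if not 0 < threshold_fraction < 1:
        raise ConfigurationError("threshold_fraction: must lie in (0, 1)")
    lo, hi = float(np.min(motion)), float(np.max(motion))
    thr = lo + threshold_fraction * (hi - lo)
    runs = _runs_above(motion >= thr)
    # boundary rule: a run touching either end may cover a clipped peak
    runs = [(s, e) for s, e in runs if s > 0 and e < motion.size]
    if not runs:
        raise NoCyclesError(
            "no-cycles: no interior peak region found above the motion threshold"
        )

    # Merge runs split by noise notches near the threshold.  The reference
    # length is the sample-weighted median run length (the length of the run
    # containing the median above-threshold sample): noise fragments are
    # numerous but short, so an unweighted median would collapse to a few
    # samples and defeat merging.
    lengths = np.array([e - s for s, e in runs])
    med_len = float(np.median(np.repeat(lengths, lengths)))
    merged: list[tuple[int, int]] = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        if s - pe < merge_gap_fraction * med_len:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    if len(merged) < 2:
        raise InsufficientCyclesError(
            f"only {len(merged)} interior peak region(s); need >= 2 for one cycle"
        )

    regions = [PeakRegion(s, e, thr) for s, e in merged]
    if refine_per_cycle:
        centers = np.array([(r.start_index + r.end_index) / 2 for r in regions])
        half_span = 0.75 * float(np.median(np.diff(centers)))
        refined = []
        for r, c in zip(regions, centers):
            a = max(0, int(c - half_span))
            b = min(motion.size, int(c + half_span))
            seg = motion[a:b]
            local_thr = float(np.min(seg) + threshold_fraction * np.ptp(seg))
            local_runs = [
                (s + a, e + a)
                for s, e in _runs_above(seg >= local_thr)
                if s + a <= c < e + a
            ]
            if local_runs:
                s, e = local_runs[0]
                refined.append(PeakRegion(s, e, local_thr))
            else:
                refined.append(r)
        regions = refined
    return regions


def fit_peak(
    motion: np.ndarray,
    region: PeakRegion,
    sampling_rate: float,
    order: int = 2,
    time: Optional[np.ndarray] = None,
) -> tuple[float, float]:
    """Polynomial least-squares peak localization within one region.

    Returns ``(peak_time, fit_rmse)``.  Time is recentred on the region
    midpoint before fitting for numerical conditioning.  The peak is the
    argmax of the fitted polynomial over the closed region interval and
    must be interior; a maximum on the boundary means the region does not
    actually bracket a peak.
    """
    if time is None:
        time = np.arange(len(motion)) / sampling_rate
    seg_t = time[region.start_index:region.end_index]
    seg_y = motion[region.start_index:region.end_index]
    if seg_t.size < order + 2:
        raise FitError(
            f"region has {seg_t.size} samples; polynomial order {order} needs >= {order + 2}"
        )
    t0 = float(seg_t.mean())
    tc = seg_t - t0
    coef = np.polyfit(tc, seg_y, order)
    fitted = np.polyval(coef, tc)
    rmse = float(np.sqrt(np.mean((fitted - seg_y) ** 2)))

    a, b = float(tc[0]), float(tc[-1])
    candidates = [a, b]
    droots = np.roots(np.polyder(coef))
    for r in droots:
        if abs(r.imag) < 1e-12 and a < r.real < b:
            candidates.append(float(r.real))
    values = np.polyval(coef, np.array(candidates))
    best = candidates[int(np.argmax(values))]
    if best == a or best == b:
        raise DegeneratePeakError(
            f"fitted maximum lies on the region boundary near t = {best + t0:.4f} s"
        )
    return best + t0, rmse


def expected_gate_times(
    peak_times: Sequence[float],
    gate_open_phase: float = 0.40,
    gate_close_phase: float = 0.60,
    period_band: tuple[float, float] = (1.0, 10.0),
) -> list[GatingCycle]:
    """Expected gate ON/OFF times for each consecutive peak pair.

    For peaks ``p_i < p_{i+1}``: the cycle period is their difference and
    the gate opens/closes at ``p_i + phase * period``.  Cycles whose period
    falls outside ``period_band`` (seconds) are flagged implausible (and a
    warning is emitted) but still returned.
    """
    peaks = np.asarray(peak_times, dtype=float)
    if peaks.size < 2:
        raise InsufficientCyclesError("need at least 2 peak times to form a cycle")
    if np.any(np.diff(peaks) <= 0):
        raise ConfigurationError("peak_times: must be strictly increasing")
    if not 0 <= gate_open_phase < gate_close_phase <= 1:
        raise ConfigurationError("gate phases: need 0 <= open < close <= 1")

    cycles = []
    for p, q in zip(peaks[:-1], peaks[1:]):
        period = float(q - p)
        ok = period_band[0] <= period <= period_band[1]
        if not ok:
            warnings.warn(
                f"cycle period {period:.3f} s outside plausibility band {period_band}",
                stacklevel=2,
            )
        cycles.append(
            GatingCycle(
                peak_time=float(p),
                cycle_period=period,
                gate_open_time=float(p + gate_open_phase * period),
                gate_close_time=float(p + gate_close_phase * period),
                plausible=ok,
            )
        )
    return cycles


def locate_gating_cycles(
    motion: np.ndarray,
    sampling_rate: float,
    time: Optional[np.ndarray] = None,
    threshold_fraction: float = 0.9,
    order: int = 2,
    gate_open_phase: float = 0.40,
    gate_close_phase: float = 0.60,
    period_band: tuple[float, float] = (1.0, 10.0),
    refine_per_cycle: bool = False,
) -> list[GatingCycle]:
    """Region finding + peak fitting + gate-time computation in one call."""
    regions = find_peak_regions(
        motion, sampling_rate, threshold_fraction, refine_per_cycle=refine_per_cycle
    )
    fits = [fit_peak(motion, r, sampling_rate, order=order, time=time) for r in regions]
    cycles = expected_gate_times(
        [t for t, _ in fits], gate_open_phase, gate_close_phase, period_band
    )
    for cyc, (_, rmse) in zip(cycles, fits):
        cyc.fit_order = order
        cyc.fit_rmse = rmse
    return cycles
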
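"""Peak regions, polynomial peak fits, expected gate times."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gatelat import PeakRegion, expected_gate_times, find_peak_regions, fit_peak
from gatelat.errors import (
    ConfigurationError,
    DegeneratePeakError,
    InsufficientCyclesError,
    NoCyclesError,
)

FS = 2000.0


def _sinusoid(n_cycles=3, period=3.0, fs=FS, pad=True):
    """Noiseless trace with peaks at 0, period, ..., n_cycles*period."""
    t0 = -period / 2 if pad else 0.0
    n = int(round((n_cycles + (1 if pad else 0)) * period * fs)) + 1
    t = np.arange(n) / fs + t0
    return t, 7.5 * (1 + np.cos(2 * np.pi * t / period))


class TestPeakRegions:
    def test_region_width_matches_analytic_duty(self):
        t, m = _sinusoid(n_cycles=4, period=3.0)
        regions = find_peak_regions(m, FS)
        expected_width = np.arccos(0.8) / np.pi * 3.0  # ~0.614 s
        assert len(regions) == 5
        for r in regions:
            assert len(r) / FS == pytest.approx(expected_width, abs=3 / FS)

    def test_truncated_peak_discarded(self):
        # trace ends mid-peak: the clipped run touches the boundary and is
        # dropped, leaving one region per *complete* peak
        T = 3.0
        t = np.arange(-T / 2, 3 * T + 1 / FS, 1 / FS)  # last peak right at the end
        m = 7.5 * (1 + np.cos(2 * np.pi * t / T))
        regions = find_peak_regions(m, FS)
        assert len(regions) == 3  # peaks at 0, T, 2T; the one at 3T is clipped

    def test_constant_signal_raises_no_cycles(self):
        with pytest.raises(NoCyclesError):
            find_peak_regions(np.full(5000, 2.0), FS)

    def test_single_peak_raises_insufficient(self):
        t, m = _sinusoid(n_cycles=0, period=3.0)
        with pytest.raises(InsufficientCyclesError):
            find_peak_regions(m, FS)

    def test_per_cycle_refinement_tracks_drift(self):
        t, m = _sinusoid(n_cycles=4, period=3.0)
        drifting = m + 0.3 * t  # slow baseline drift
        coarse = find_peak_regions(drifting, FS)
        refined = find_peak_regions(drifting, FS, refine_per_cycle=True)
        assert len(refined) == len(coarse)
        fits_r = [fit_peak(drifting, r, FS, time=t)[0] for r in refined]
        for p in fits_r:
            # true peaks of the underlying sinusoid sit at multiples of 3 s
            # (the 0.3 mm/s drift shifts each cosine peak by < 20 ms)
            assert p == pytest.approx(3.0 * round(p / 3.0), abs=0.05)


class TestFitPeak:
    def test_parabola_vertex_recovered_exactly(self):
        t = np.arange(0, 2.0, 1 / FS)
        y = 5.0 - (t - 1.0) ** 2
        region = PeakRegion(int(0.5 * FS), int(1.5 * FS), threshold_used=4.0)
        peak, rmse = fit_peak(y, region, FS, order=2, time=t)
        assert peak == pytest.approx(1.000, abs=1e-9)
        assert rmse == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("order", [2, 4])
    def test_noiseless_sinusoid_peak_within_one_sample(self, order):
        t, m = _sinusoid(n_cycles=2, period=3.0)
        regions = find_peak_regions(m, FS)
        # middle region covers the peak at t = 3.0 s
        peak, _ = fit_peak(m, regions[1], FS, order=order, time=t)
        assert peak == pytest.approx(3.000, abs=1 / FS)

    def test_agrees_with_dense_grid_argmax(self):
        # independent oracle: evaluate the same least-squares polynomial on a
        # 1 microsecond grid and take its argmax
        rng = np.random.default_rng(7)
        t, m = _sinusoid(n_cycles=2, period=3.0)
        m = m + rng.normal(0, 0.05, m.size)
        region = find_peak_regions(m, FS)[1]
        peak, _ = fit_peak(m, region, FS, order=2, time=t)
        seg_t = t[region.start_index:region.end_index]
        seg_y = m[region.start_index:region.end_index]
        tc = seg_t - seg_t.mean()
        coef = np.polyfit(tc, seg_y, 2)
        grid = np.arange(tc[0], tc[-1], 1e-6)
        oracle = grid[np.argmax(np.polyval(coef, grid))] + seg_t.mean()
        assert peak == pytest.approx(oracle, abs=1e-6)

    def test_monotone_region_is_degenerate(self):
        t = np.arange(0, 2.0, 1 / FS)
        y = t.copy()  # no interior maximum
        region = PeakRegion(100, 900, threshold_used=0.0)
        with pytest.raises(DegeneratePeakError):
            fit_peak(y, region, FS, time=t)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.05, 50.0),
        offset=st.floats(-40.0, 40.0),
    )
    def test_scale_and_offset_invariance(self, scale, offset):
        t, m = _sinusoid(n_cycles=2, period=3.0)
        base_region = find_peak_regions(m, FS)[1]
        base_peak, _ = fit_peak(m, base_region, FS, time=t)
        m2 = scale * m + offset
        region2 = find_peak_regions(m2, FS)[1]
        peak2, _ = fit_peak(m2, region2, FS, time=t)
        assert abs(peak2 - base_peak) <= 1 / FS


class TestGateTimes:
    def test_default_window_arithmetic(self):
        cycles = expected_gate_times([0.0, 3.0])
        assert len(cycles) == 1
        assert cycles[0].gate_open_time == pytest.approx(1.200, abs=1e-12)
        assert cycles[0].gate_close_time == pytest.approx(1.800, abs=1e-12)

    def test_per_cycle_period(self):
        cycles = expected_gate_times([0.0, 3.0, 6.1])
        assert cycles[1].cycle_period == pytest.approx(3.1, abs=1e-12)
        assert cycles[1].gate_open_time == pytest.approx(4.240, abs=1e-12)

    def test_gate_duration_is_fifth_of_period(self):
        # 40%-60% window: duration exactly 0.2 x per-cycle period
        cycles = expected_gate_times([0.0, 2.9, 6.2, 9.0])
        for c in cycles:
            assert c.gate_close_time - c.gate_open_time == pytest.approx(
                0.2 * c.cycle_period, abs=1e-9
            )

    def test_single_peak_insufficient(self):
        with pytest.raises(InsufficientCyclesError):
            expected_gate_times([1.0])

    def test_non_monotone_rejected(self):
        with pytest.raises(ConfigurationError):
            expected_gate_times([0.0, 3.0, 2.5])

    def test_implausible_period_flagged(self):
        with pytest.warns(UserWarning):
            cycles = expected_gate_times([0.0, 0.5])  # 0.5 s: outside 1-10 s band
        assert not cycles[0].plausible
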
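"""Simulator: waveform shape, determinism, ground-truth construction."""

import dataclasses

import numpy as np
import pytest

from gatelat import ScenarioConfig, simulate_motion, simulate_session, time_axis
from gatelat.errors import ConfigurationError, InfeasibleScenarioError


def _noiseless(amplitude=10.0, period=3.0, n_cycles=3, fs=2000.0, **kw):
    return ScenarioConfig(
        amplitude=amplitude, period=period, n_cycles=n_cycles, sampling_rate=fs, **kw
    ).without_noise()


class TestMotion:
    def test_noiseless_closed_form(self):
        cfg = _noiseless(amplitude=10.0, period=3.0)
        t = time_axis(cfg)
        m = simulate_motion(cfg)
        assert np.ptp(m) == pytest.approx(10.0, abs=1e-9)
        # peaks sit at integer multiples of the period, one period apart
        for k in range(cfg.n_cycles + 1):
            i = np.argmin(np.abs(t - k * cfg.period))
            assert m[i] == pytest.approx(10.0, abs=1e-9)
        # half-period padding puts the first/last peaks in the interior
        assert t[0] == pytest.approx(-cfg.period / 2)
        assert t[-1] == pytest.approx(cfg.n_cycles * cfg.period + cfg.period / 2)

    def test_duty_fraction_above_90pct_threshold(self):
        # analytically, cos(2*pi*t/T) >= 0.8 on a fraction arccos(0.8)/pi
        # of each cycle; check the sampled noiseless trace matches
        cfg = _noiseless(amplitude=10.0, period=3.0, n_cycles=10, fs=10_000.0)
        m = simulate_motion(cfg)
        thr = m.min() + 0.9 * np.ptp(m)
        expected = np.arccos(0.8) / np.pi
        assert np.mean(m >= thr) == pytest.approx(expected, abs=2e-3)

    def test_determinism_under_fixed_seed(self):
        cfg = ScenarioConfig(amplitude=12, period=4, n_cycles=3,
                             sampling_rate=2000, seed=42)
        assert np.array_equal(simulate_motion(cfg), simulate_motion(cfg))


class TestSession:
    def test_ground_truth_counts_and_identity(self):
        cfg = ScenarioConfig(amplitude=15, period=3, n_cycles=30,
                             sampling_rate=2000, seed=3)
        _, gt = simulate_session(cfg)
        assert len(gt) == 30
        for c in gt.cycles:
            # construction identity: beam-on minus gate-open equals the sum
            # of the injected component latencies, exactly
            total_on = (c.true_beam_on_time - c.true_gate_open_time) * 1000.0
            assert total_on == pytest.approx(c.injected_rpm_on + c.injected_cyc_on, abs=1e-6)
            total_off = (c.true_beam_off_time - c.true_gate_close_time) * 1000.0
            assert total_off == pytest.approx(c.injected_rpm_off + c.injected_cyc_off, abs=1e-6)
            assert c.true_gate_open_time == pytest.approx(
                c.true_peak_time + cfg.gate_open_phase * cfg.period, abs=1e-9
            )

    def test_pooled_reference_means_compose(self):
        # injecting the pooled ON means with zero spread forces every cycle's
        # beam-on minus gate-open to 104.20 + 108.29 = 212.49 ms
        cfg = _noiseless(n_cycles=3)
        cfg = dataclasses.replace(
            cfg, rpm_on_latency_mean=104.20, cyc_on_latency_mean=108.29
        )
        _, gt = simulate_session(cfg)
        for c in gt.cycles:
            total = (c.true_beam_on_time - c.true_gate_open_time) * 1000.0
            assert total == pytest.approx(212.49, abs=1e-6)

    def test_session_determinism_bit_identical(self):
        cfg = ScenarioConfig(amplitude=8, period=3, n_cycles=2,
                             sampling_rate=2000, seed=99)
        r1, g1 = simulate_session(cfg)
        r2, g2 = simulate_session(cfg)
        for ch in ("time", "motion", "trigger", "beam"):
            assert np.array_equal(getattr(r1, ch), getattr(r2, ch))
        assert g1.cycles == g2.cycles

    def test_latency_draws_truncated_at_zero(self):
        cfg = ScenarioConfig(
            amplitude=10, period=4, n_cycles=20, sampling_rate=2000, seed=5,
            rpm_on_latency_mean=2.0, rpm_on_latency_sd=10.0,
        )
        _, gt = simulate_session(cfg)
        assert all(c.injected_rpm_on >= 0 for c in gt.cycles)

    def test_zero_latency_trigger_coincides_with_gate_open(self, noiseless_session):
        cfg = _noiseless(n_cycles=2)
        cfg = dataclasses.replace(
            cfg,
            rpm_on_latency_mean=0.0, rpm_off_latency_mean=0.0,
            cyc_on_latency_mean=0.0, cyc_off_latency_mean=0.0,
        )
        rec, gt = simulate_session(cfg)
        one_sample = 1.0 / cfg.sampling_rate
        for c in gt.cycles:
            assert c.true_trigger_on_time == pytest.approx(c.true_gate_open_time, abs=1e-12)
            # the waveform actually departs from 0 V at that instant
            i = np.searchsorted(rec.time, c.true_trigger_on_time)
            assert rec.trigger[max(0, i - 1)] == pytest.approx(0.0, abs=1e-9)
            j = np.searchsorted(rec.time, c.true_trigger_on_time + one_sample)
            assert rec.trigger[j] > 0.0


class TestValidation:
    @pytest.mark.parametrize(
        "field, value",
        [
            ("amplitude", 0.0),
            ("period", -1.0),
            ("sampling_rate", 500.0),
            ("rpm_on_latency_mean", -5.0),
            ("gate_open_phase", 0.7),   # >= close phase
        ],
    )
    def test_invalid_config_names_field(self, field, value):
        cfg = ScenarioConfig(amplitude=10, period=3, n_cycles=2, sampling_rate=2000)
        cfg = dataclasses.replace(cfg, **{field: value})
        with pytest.raises(ConfigurationError) as exc:
            simulate_motion(cfg)
        assert field.split("_")[0] in str(exc.value)

    def test_infeasible_gate_interval(self):
        cfg = ScenarioConfig(
            amplitude=10, period=3, n_cycles=2, sampling_rate=2000,
            gate_open_phase=0.4, gate_close_phase=0.40005,
        )
        with pytest.raises(InfeasibleScenarioError):
            simulate_session(cfg)
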
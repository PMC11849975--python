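"""Wave segmentation, dose metrics, calibration and energy arithmetic."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from blastdose.dosimetry import (
    DropSummary,
    SegmentationParams,
    calibration_error,
    estimate_baseline,
    expected_static_pressure,
    pe_ratio,
    potential_energy,
    segment_waves,
    summarize_drop,
    summarize_replicates,
)

from conftest import brute_force_segment


class TestEstimateBaseline:
    def test_constant_trace(self, make_pressure_trace):
        trace = make_pressure_trace(np.arange(100.0), np.full(100, 3.0))
        baseline, sd = estimate_baseline(trace, window_ms=50)
        assert baseline == 3.0 and sd == 0.0

    def test_spike_outside_window_ignored(self, make_pressure_trace):
        p = np.zeros(1000)
        p[100] = 500.0
        trace = make_pressure_trace(np.arange(1000.0), p)
        baseline, _ = estimate_baseline(trace, window_ms=200, mode="trailing")
        assert baseline == 0.0

    def test_gaussian_noise_recovered(self, make_pressure_trace):
        rng = np.random.default_rng(42)
        n = 10_000
        trace = make_pressure_trace(np.arange(float(n)), 2.0 + rng.normal(0, 0.5, n))
        baseline, sd = estimate_baseline(trace, window_ms=n)
        assert baseline == pytest.approx(2.0, abs=0.02)  # ~4 SE of the mean
        assert sd == pytest.approx(0.5, rel=0.05)

    def test_short_window_rejected(self, make_pressure_trace):
        trace = make_pressure_trace(np.arange(100.0), np.zeros(100))
        with pytest.raises(ValueError, match="at least 10"):
            estimate_baseline(trace, window_ms=5)


class TestSegmentWaves:
    def test_flat_trace_no_waves(self, make_pressure_trace):
        trace = make_pressure_trace(np.arange(100.0), np.zeros(100))
        assert segment_waves(trace, 0.0, 1.0) == []

    def test_three_rectangular_pulses(self, rectangular_pulse_trace):
        trace = rectangular_pulse_trace(
            [(100, 10, 100.0), (300, 10, 50.0), (500, 10, 25.0)]
        )
        waves = segment_waves(trace, baseline_kpa=0.0, exceedance_kpa=1.0)
        assert [w.peak_kpa for w in waves] == [100.0, 50.0, 25.0]
        assert [w.mean_kpa for w in waves] == [100.0, 50.0, 25.0]
        assert [w.index for w in waves] == [1, 2, 3]

    def test_half_sine_mean_is_2_over_pi(self, make_pressure_trace):
        # closed form: the time average of A sin(pi t / w) over (0, w) is 2A/pi
        amplitude, width, dt = 200.0, 50.0, 0.01
        t = np.arange(0.0, 200.0, dt)
        p = np.where(
            (t >= 50) & (t <= 50 + width),
            amplitude * np.sin(np.pi * (t - 50) / width),
            0.0,
        )
        waves = segment_waves(make_pressure_trace(t, p), 0.0, 1e-6, min_duration_ms=0)
        assert len(waves) == 1
        assert waves[0].peak_kpa == pytest.approx(amplitude, rel=1e-6)
        assert waves[0].mean_kpa == pytest.approx(2 * amplitude / np.pi, rel=1e-3)

    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        """Randomized pulse fixtures agree with a literal open/close scan."""
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        n = 300
        p = rng.normal(0, 0.3, n)
        for _ in range(rng.integers(0, 6)):
            start = rng.integers(0, n - 20)
            width = rng.integers(1, 20)
            p[start : start + width] += rng.uniform(2, 100)
        t = np.arange(float(n))
        threshold = 1.0
        from blastdose.trace_io import DeviceConfig, PressureTrace

        trace = PressureTrace(
            times_ms=t,
            pressure_kpa=p,
            device=DeviceConfig(20, "clamp", 100, 108, 19.1),
        )
        waves = segment_waves(trace, 0.0, threshold, min_duration_ms=0.0)
        oracle = brute_force_segment(t, p, threshold)
        assert len(waves) == len(oracle)
        for wave, (i, j, peak, mean) in zip(waves, oracle):
            assert wave.start_ms == t[i] and wave.end_ms == t[j]
            assert wave.peak_kpa == pytest.approx(peak)
            assert wave.mean_kpa == pytest.approx(mean)

    def test_waves_disjoint_ordered_within_span(self, rectangular_pulse_trace):
        trace = rectangular_pulse_trace([(50, 30, 80.0), (200, 5, 40.0), (700, 100, 20.0)])
        waves = segment_waves(trace, 0.0, 1.0)
        for a, b in zip(waves, waves[1:]):
            assert a.end_ms <= b.start_ms
        assert sum(w.duration_ms for w in waves) <= trace.duration_ms

    def test_min_duration_discards_blips(self, rectangular_pulse_trace):
        trace = rectangular_pulse_trace([(100, 1, 100.0), (300, 10, 50.0)], dt=1.0)
        waves = segment_waves(trace, 0.0, 1.0, min_duration_ms=2.0)
        assert [w.peak_kpa for w in waves] == [50.0]


class TestSummarizeDrop:
    def test_two_pulses_one_interval(self, rectangular_pulse_trace):
        trace = rectangular_pulse_trace([(100, 10, 100.0), (180, 10, 60.0)])
        summary = summarize_drop(trace, SegmentationParams(exceedance_kpa=1.0))
        assert summary.n_waves == 2
        assert summary.inter_wave_intervals_ms == (80.0,)
        assert summary.maximal_pressure_kpa == 100.0

    def test_single_pulse_no_intervals(self, rectangular_pulse_trace):
        trace = rectangular_pulse_trace([(100, 10, 100.0)])
        summary = summarize_drop(trace, SegmentationParams(exceedance_kpa=1.0))
        assert summary.inter_wave_intervals_ms == ()

    def test_max_pressure_invariant_to_segmentation(self, rectangular_pulse_trace):
        trace = rectangular_pulse_trace([(100, 10, 100.0), (300, 10, 5.0)])
        for exceedance in (1.0, 10.0, 50.0):
            s = summarize_drop(trace, SegmentationParams(exceedance_kpa=exceedance))
            assert s.maximal_pressure_kpa == 100.0

    def test_max_equals_top_wave_peak(self, rectangular_pulse_trace):
        trace = rectangular_pulse_trace([(100, 10, 100.0), (300, 10, 40.0)])
        s = summarize_drop(trace, SegmentationParams(exceedance_kpa=1.0))
        assert s.maximal_pressure_kpa == max(w.peak_kpa for w in s.waves)


class TestSummarizeReplicates:
    def _drops(self, maxima, device):
        return [
            DropSummary(
                maximal_pressure_kpa=m,
                waves=(),
                baseline_kpa=0.0,
                noise_sd_kpa=0.0,
                device=device,
                drop_index=i + 1,
            )
            for i, m in enumerate(maxima)
        ]

    def test_identical_maxima(self, device):
        rep = summarize_replicates(self._drops([100.0, 100.0, 100.0], device))
        assert rep.mean_max_pressure_kpa == 100.0
        assert rep.sem_max_pressure_kpa == 0.0
        assert rep.rsd_percent == 0.0

    def test_hand_case_90_100_110(self, device):
        # sample SD (n-1) of {90,100,110} is 10 -> SEM 10/sqrt(3), RSD 10%
        rep = summarize_replicates(self._drops([90.0, 100.0, 110.0], device))
        assert rep.mean_max_pressure_kpa == 100.0
        assert rep.sem_max_pressure_kpa == pytest.approx(10 / np.sqrt(3), abs=1e-12)
        assert rep.sem_max_pressure_kpa == pytest.approx(5.77, abs=0.005)
        assert rep.rsd_percent == pytest.approx(10.0, abs=1e-12)

    @given(
        maxima=st.lists(st.floats(1, 1000), min_size=2, max_size=10),
        scale=st.floats(0.1, 50),
    )
    def test_rsd_scale_invariant_sem_linear(self, maxima, scale):
        from blastdose.trace_io import DeviceConfig

        device = DeviceConfig(20, "clamp", 100, 108, 19.1)
        base = summarize_replicates(self._drops(maxima, device))
        scaled = summarize_replicates(self._drops([scale * m for m in maxima], device))
        assert scaled.rsd_percent == pytest.approx(base.rsd_percent, rel=1e-9, abs=1e-9)
        assert scaled.sem_max_pressure_kpa == pytest.approx(
            scale * base.sem_max_pressure_kpa, rel=1e-9, abs=1e-9
        )

    def test_single_drop_rejected(self, device):
        with pytest.raises(ValueError, match=">= 2"):
            summarize_replicates(self._drops([100.0], device))


class TestStaticCalibration:
    def test_zero_mass(self):
        assert expected_static_pressure(0.0, 14.5) == 0.0

    def test_one_kg_on_14_5_mm_barrel(self):
        # (1 kg * 9.80665) / (pi * 0.00725^2 m^2) = 59.4 kPa
        assert expected_static_pressure(1000.0, 14.5) == pytest.approx(59.39, abs=0.01)

    @given(mass=st.floats(1, 5000), diameter=st.floats(5, 50))
    def test_linear_in_mass(self, mass, diameter):
        assert expected_static_pressure(2 * mass, diameter) == pytest.approx(
            2 * expected_static_pressure(mass, diameter), rel=1e-12
        )

    @pytest.mark.parametrize(
        "measured, expected, pct",
        [(50.0, 50.0, 0.0), (55.0, 50.0, 10.0), (45.0, 50.0, -10.0)],
    )
    def test_calibration_error_sign_convention(self, measured, expected, pct):
        assert calibration_error(measured, expected) == pytest.approx(pct)

    def test_calibration_error_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            calibration_error(10.0, 0.0)


class TestPotentialEnergy:
    def test_100g_from_108cm(self):
        assert potential_energy(100.0, 108.0) == pytest.approx(1.059, abs=0.001)

    def test_energy_ratio_of_equal_pressure_settings(self):
        # 200 g from 27 cm carries half the energy of 100 g from 108 cm
        assert pe_ratio((200.0, 27.0), (100.0, 108.0)) == pytest.approx(50.0)

    @given(mass=st.floats(1, 1000), height=st.floats(1, 500))
    def test_self_ratio_is_100(self, mass, height):
        assert pe_ratio((mass, height), (mass, height)) == pytest.approx(100.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            pe_ratio((100.0, 100.0), (100.0, 0.0))
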
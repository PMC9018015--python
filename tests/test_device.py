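"""Sensor calculators, Poisson pulse simulation, and interrupt contention."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lumipulse import (
    AcquisitionConfig,
    PulseTrain,
    SensorSpec,
    counts_to_frequency,
    detection_limit_irradiance,
    dynamic_range_orders,
    integration_gain,
    irradiance_to_frequency,
    mcu_acquire,
    round_sig,
    simulate_pulse_train,
)

from conftest import make_train, replay_counts


class TestSpecCalculators:
    def test_irradiance_to_frequency_dark_only(self):
        assert irradiance_to_frequency(0.0) == pytest.approx(0.1)

    def test_irradiance_at_detection_limit_matches_dark_floor(self):
        # inverse of the LOD arithmetic: E = f_D / R gives back f_D of signal
        spec = SensorSpec(dark_frequency=1e-12, responsivity=2300.0)
        assert irradiance_to_frequency(0.1 / 2300.0, spec) == pytest.approx(0.1, rel=1e-9)

    def test_irradiance_saturates_at_max_frequency(self):
        assert irradiance_to_frequency(1e6) == 1e6

    def test_negative_irradiance_rejected(self):
        with pytest.raises(ValueError):
            irradiance_to_frequency(-1e-9)

    @pytest.mark.parametrize(
        "counts,window,sig,expected",
        [
            (6, 300.0, 1, 0.02),  # in-dish dark floor readout
            (18, 300.0, 1, 0.06),  # basal transactivation readout
            (142, 300.0, 2, 0.47),  # brightest firefly signal measured
            (0, 17.0, None, 0.0),
        ],
    )
    def test_counts_to_frequency(self, counts, window, sig, expected):
        assert counts_to_frequency(counts, window, sig) == pytest.approx(expected)

    def test_counts_to_frequency_rejects_bad_window(self):
        with pytest.raises(ValueError):
            counts_to_frequency(5, 0.0)

    def test_dynamic_range_defaults_is_seven_orders(self):
        assert dynamic_range_orders(SensorSpec()) == pytest.approx(7.0)

    @pytest.mark.parametrize(
        "f_d,f_max,expected", [(1.0, 1000.0, 3.0), (0.5, 0.5001, 0.0)]
    )
    def test_dynamic_range_log_identity(self, f_d, f_max, expected):
        spec = SensorSpec(dark_frequency=f_d, max_frequency=f_max)
        assert dynamic_range_orders(spec) == pytest.approx(expected, abs=1e-3)

    def test_dynamic_range_undefined_for_zero_dark(self):
        with pytest.raises(ValueError):
            dynamic_range_orders(SensorSpec(dark_frequency=0.0))

    def test_detection_limit_default_rounds_to_40(self):
        lod = detection_limit_irradiance(SensorSpec())
        assert lod == pytest.approx(43.478, abs=1e-3)
        assert round_sig(lod, 1) == 40.0

    def test_detection_limit_scales_with_dark_frequency(self):
        assert detection_limit_irradiance(
            SensorSpec(dark_frequency=0.2)
        ) == pytest.approx(0.2 / 2300.0 * 1e6)
        assert detection_limit_irradiance(SensorSpec(dark_frequency=0.0)) == 0.0

    @pytest.mark.parametrize(
        "a,b,expected", [(300.0, 1200.0, 4.0), (60.0, 60.0, 1.0), (300.0, 7200.0, 24.0)]
    )
    def test_integration_gain_is_window_ratio(self, a, b, expected):
        assert integration_gain(a, b) == expected

    def test_integration_gain_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            integration_gain(0.0, 300.0)

    @pytest.mark.parametrize(
        "x,sig,expected",
        [(0.47333, 2, 0.47), (0.475, 2, 0.48), (0.02333, 1, 0.02), (-0.475, 2, -0.48), (0.0, 3, 0.0)],
    )
    def test_round_sig_half_away_from_zero(self, x, sig, expected):
        assert round_sig(x, sig) == expected

    @settings(derandomize=True, max_examples=50)
    @given(E=st.floats(min_value=0, max_value=1e9, allow_nan=False))
    def test_frequency_never_exceeds_max_and_is_monotone(self, E):
        spec = SensorSpec()
        f = irradiance_to_frequency(E, spec)
        assert f <= spec.max_frequency
        assert irradiance_to_frequency(E * 2, spec) >= f


class TestSensorSpecInvariants:
    def test_dark_below_max_required(self):
        with pytest.raises(ValueError):
            SensorSpec(dark_frequency=2e6)

    def test_positive_responsivity_required(self):
        with pytest.raises(ValueError):
            SensorSpec(responsivity=0.0)

    def test_spectral_range_ordered(self):
        with pytest.raises(ValueError):
            SensorSpec(spectral_range=(1050.0, 320.0))


class TestPulseSimulation:
    def test_constant_rate_reproduces_basal_count_level(self):
        # 0.02 Hz total over 5-min windows -> ~6 pulses/window on average
        spec = SensorSpec(dark_frequency=0.02)
        cfg = AcquisitionConfig(n_wells=1, total_duration=600000.0, seed=7)
        train = simulate_pulse_train(lambda t: np.zeros_like(t), spec, cfg, "A")
        counts = mcu_acquire([train], cfg)[0].counts
        lam = 0.02 * 300.0
        se = math.sqrt(lam / len(counts))
        assert abs(counts.mean() - lam) < 3 * se

    def test_index_of_dispersion_near_unity(self):
        # Poisson counts: variance/mean ~ 1 across 1e4 windows
        spec = SensorSpec(dark_frequency=1e-12)
        cfg = AcquisitionConfig(
            n_wells=1, total_duration=1e4, integration_window=1.0,
            interrupt_dead_time=0.0, seed=11,
        )
        train = simulate_pulse_train(lambda t: np.full_like(t, 1.0), spec, cfg, "A")
        counts = mcu_acquire([train], cfg)[0].counts
        disp = counts.var() / counts.mean()
        assert 0.9 < disp < 1.1

    def test_zero_rate_zero_dark_gives_empty_train(self):
        spec = SensorSpec(dark_frequency=0.0)
        cfg = AcquisitionConfig(n_wells=1, total_duration=1000.0, seed=0)
        train = simulate_pulse_train(lambda t: np.zeros_like(t), spec, cfg, "A")
        assert len(train) == 0

    def test_negative_rate_rejected(self):
        cfg = AcquisitionConfig(n_wells=1, total_duration=1000.0, seed=0)
        with pytest.raises(ValueError):
            simulate_pulse_train(lambda t: np.full_like(t, -1.0), SensorSpec(), cfg, "A")

    def test_seed_reproducibility(self):
        cfg = AcquisitionConfig(n_wells=1, total_duration=5000.0, seed=42)
        spec = SensorSpec(dark_frequency=0.5)
        a = simulate_pulse_train(lambda t: np.zeros_like(t), spec, cfg, "A")
        b = simulate_pulse_train(lambda t: np.zeros_like(t), spec, cfg, "A")
        assert np.array_equal(a.events, b.events)

    def test_time_varying_rate_tracks_intensity(self):
        # ramp 0 -> 2 Hz: second half of the session holds ~3x the events
        spec = SensorSpec(dark_frequency=1e-12)
        cfg = AcquisitionConfig(n_wells=1, total_duration=20000.0, integration_window=10000.0, seed=5)
        train = simulate_pulse_train(lambda t: 2.0 * t / 20000.0, spec, cfg, "A")
        first, second = mcu_acquire([train], cfg)[0].counts
        assert second / max(first, 1) == pytest.approx(3.0, rel=0.15)


class TestPulseTrainInvariants:
    def test_unsorted_events_rejected(self):
        with pytest.raises(ValueError):
            make_train([2.0, 1.0])

    def test_events_outside_session_rejected(self):
        with pytest.raises(ValueError):
            make_train([1.0, 11.0], duration=10.0)


class TestMcuAcquire:
    def test_zero_dead_time_equals_exact_histogram(self):
        cfg = AcquisitionConfig(
            n_wells=2, total_duration=10.0, integration_window=5.0, interrupt_dead_time=0.0
        )
        a = make_train([0.5, 1.5, 6.0], "A")
        b = make_train([0.5, 7.0, 9.9], "B")
        series = mcu_acquire([a, b], cfg)
        assert series[0].counts.tolist() == [2, 1]
        assert series[1].counts.tolist() == [1, 2]

    def test_hand_traced_contention_loss(self):
        # B's pulse lands 0.1 ms after A's within a 1 ms dead time: B is lost
        cfg = AcquisitionConfig(
            n_wells=2, total_duration=10.0, integration_window=10.0, interrupt_dead_time=0.001
        )
        a = make_train([1.0000], "A")
        b = make_train([1.0001], "B")
        series = mcu_acquire([a, b], cfg)
        assert series[0].counts.tolist() == [1]
        assert series[1].counts.tolist() == [0]

    def test_simultaneous_events_tie_break_by_well_order(self):
        cfg = AcquisitionConfig(
            n_wells=2, total_duration=10.0, integration_window=10.0, interrupt_dead_time=0.5
        )
        a = make_train([3.0], "A")
        b = make_train([3.0], "B")
        series = mcu_acquire([a, b], cfg)
        assert series[0].counts.tolist() == [1]  # lower well index serviced first
        assert series[1].counts.tolist() == [0]

    def test_total_counts_non_increasing_in_dead_time(self):
        rng = np.random.default_rng(3)
        events = np.unique(rng.uniform(0, 100.0, 500))
        totals = []
        for tau in [0.0, 0.01, 0.1, 1.0, 10.0]:
            cfg = AcquisitionConfig(
                n_wells=1, total_duration=100.0, integration_window=10.0,
                interrupt_dead_time=tau,
            )
            train = PulseTrain("A", events, 100.0)
            totals.append(mcu_acquire([train], cfg)[0].counts.sum())
        assert totals == sorted(totals, reverse=True)
        cfg0 = AcquisitionConfig(
            n_wells=1, total_duration=100.0, integration_window=10.0, interrupt_dead_time=0.0
        )
        raw = mcu_acquire([PulseTrain("A", events, 100.0)], cfg0)[0].counts.sum()
        assert totals[0] == raw

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_agrees_with_brute_force_replay(self, seed):
        rng = np.random.default_rng(seed)
        n_wells = int(rng.integers(1, 5))
        trains = [
            PulseTrain(
                f"W{w}",
                np.unique(rng.uniform(0, 50.0, int(rng.integers(50, 300)))),
                50.0,
            )
            for w in range(n_wells)
        ]
        cfg = AcquisitionConfig(
            n_wells=n_wells, total_duration=50.0, integration_window=5.0,
            interrupt_dead_time=float(rng.uniform(0, 0.2)),
        )
        got = [s.counts.tolist() for s in mcu_acquire(trains, cfg)]
        assert got == replay_counts(trains, cfg)

    def test_luciferase_rates_barely_contend(self):
        # brightest measured signal (0.47 Hz) with a companion well:
        # expected collision losses ~ N * lambda * tau ~ 0.05 events
        spec = SensorSpec(dark_frequency=1e-12)
        cfg_tau = AcquisitionConfig(
            n_wells=2, total_duration=36000.0, interrupt_dead_time=5e-6, seed=8
        )
        cfg_0 = AcquisitionConfig(
            n_wells=2, total_duration=36000.0, interrupt_dead_time=0.0, seed=8
        )
        bright = simulate_pulse_train(
            lambda t: np.full_like(t, 0.47), spec, cfg_tau, "bright",
            rng=np.random.default_rng(8),
        )
        dim = simulate_pulse_train(
            lambda t: np.full_like(t, 0.06), spec, cfg_tau, "dim",
            rng=np.random.default_rng(9),
        )
        with_tau = sum(s.counts.sum() for s in mcu_acquire([bright, dim], cfg_tau))
        without = sum(s.counts.sum() for s in mcu_acquire([bright, dim], cfg_0))
        assert without - with_tau <= 2  # practically lossless at reporter rates

    def test_mismatched_session_bounds_rejected(self):
        cfg = AcquisitionConfig(n_wells=2, total_duration=10.0, integration_window=5.0)
        with pytest.raises(ValueError):
            mcu_acquire([make_train([1.0], duration=10.0), make_train([1.0], duration=20.0)], cfg)
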
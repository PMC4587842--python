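"""Burst classification, rhythmicity, rate statistics, and passive estimates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gastromill.errors import InvalidParameterError
from gastromill.metrics import (
    SpikeTrain,
    TempMeasurement,
    burst_statistics,
    classify_bursts,
    delta_leak_from_resistances,
    detect_spikes,
    estimate_input_resistance,
    fit_temperature_trend,
    is_rhythmic,
)
from gastromill.synth import PassiveTraceSpec, gen_passive_trace

from conftest import oracle_bursts, random_spike_train


def make_train(times, window=None):
    times = np.asarray(times, dtype=float)
    if window is None:
        hi = float(times[-1]) + 3.0 if times.size else 10.0
        window = (0.0, hi)
    return SpikeTrain("u", times, window)


class TestClassifyBursts:
    def test_minimal_printed_burst(self):
        bursts = classify_bursts(make_train([0.0, 0.3, 0.6, 0.9]))
        assert len(bursts) == 1
        assert bursts[0].n_spikes == 4
        assert bursts[0].duration == pytest.approx(0.9)

    def test_three_spikes_is_not_a_burst(self):
        assert classify_bursts(make_train([0.0, 0.5, 1.0])) == []

    def test_boundary_conventions(self):
        # ISI of exactly 1 s splits the run but the <2 s gap re-merges;
        # a gap of exactly 2 s separates events.
        t = [0.0, 1.0, 1.5, 2.0, 2.5]
        bursts = classify_bursts(make_train(t))
        assert len(bursts) == 1 and bursts[0].n_spikes == 5
        t = [0.0, 0.2, 0.4, 0.6, 2.6, 2.8, 3.0, 3.2]
        bursts = classify_bursts(make_train(t))
        assert [b.n_spikes for b in bursts] == [4, 4]

    def test_merge_below_two_seconds(self):
        t = [0.0, 0.2, 0.4, 2.3, 2.5, 2.7]
        bursts = classify_bursts(make_train(t))
        assert len(bursts) == 1 and bursts[0].n_spikes == 6

    def test_empty_train(self):
        assert classify_bursts(make_train([])) == []

    def test_spikes_outside_window_ignored(self):
        inside = [5.0, 5.2, 5.4, 5.6]
        train = make_train(inside + [20.5], window=(0.0, 10.0))
        bursts = classify_bursts(train)
        assert len(bursts) == 1 and bursts[0].n_spikes == 4

    def test_matches_oracle_on_random_trains(self):
        rng = np.random.default_rng(20260928)
        for _ in range(1000):
            times = random_spike_train(rng)
            lo, hi = 0.0, (times[-1] + 1.0 if times.size else 1.0)
            got = classify_bursts(SpikeTrain("u", times, (lo, hi)))
            want = oracle_bursts(times, lo, hi)
            assert len(got) == len(want)
            for b, w in zip(got, want):
                assert b.n_spikes == w.size
                assert b.onset == pytest.approx(w[0])
                assert b.offset == pytest.approx(w[-1])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 50.0, allow_nan=False), min_size=0,
                    max_size=40),
           st.floats(-5.0, 5.0, allow_nan=False))
    def test_time_shift_invariance(self, raw, shift):
        times = np.unique(np.round(np.asarray(raw), 4))
        b0 = classify_bursts(SpikeTrain("u", times, (-1.0, 51.0)))
        b1 = classify_bursts(SpikeTrain("u", times + shift,
                                        (-1.0 + shift, 51.0 + shift)))
        assert [b.n_spikes for b in b0] == [b.n_spikes for b in b1]
        for x, y in zip(b0, b1):
            assert y.onset - x.onset == pytest.approx(shift, abs=1e-9)


class TestRhythmicity:
    def test_counts(self):
        b2 = classify_bursts(make_train(
            [0, .1, .2, .3, 10, 10.1, 10.2, 10.3]))
        assert not is_rhythmic(b2, 100.0)
        b3 = classify_bursts(make_train(
            [0, .1, .2, .3, 10, 10.1, 10.2, 10.3, 20, 20.1, 20.2, 20.3]))
        assert is_rhythmic(b3, 100.0)

    def test_time_scale_covariance(self):
        t = np.array([0, .1, .2, .3, 10, 10.1, 10.2, 10.3,
                      20, 20.1, 20.2, 20.3])
        flag100 = is_rhythmic(classify_bursts(make_train(t)), 100.0)
        flag50 = is_rhythmic(classify_bursts(make_train(t * 0.5)), 50.0)
        assert flag100 == flag50

    def test_bad_window(self):
        with pytest.raises(InvalidParameterError):
            is_rhythmic([], 0.0)


class TestBurstStatistics:
    def test_closed_forms(self):
        bursts = classify_bursts(make_train([0, .5, 1.0, 1.5, 2.0]))
        stats = burst_statistics(bursts, window=100.0)
        assert stats.mean_intraburst_freq == pytest.approx((5 - 1) / 2.0)

        t = ([10 + .1 * i for i in range(4)] + [22 + .1 * i for i in range(4)]
             + [34 + .1 * i for i in range(4)])
        stats = burst_statistics(classify_bursts(make_train(t)), window=100.0)
        assert stats.mean_cycle_period == pytest.approx(12.0)
        assert stats.mean_spikes_per_burst == pytest.approx(4.0)

    def test_rate_normalization(self):
        t = [i * 12 + j * 0.1 for i in range(4) for j in range(4)]
        stats = burst_statistics(classify_bursts(make_train(t)), window=50.0)
        assert stats.bursts_per_100s == pytest.approx(8.0)


class TestDetectSpikes:
    def test_flat_trace(self):
        t = np.arange(0, 1, 1e-4)
        train = detect_spikes(t, np.full_like(t, -70.0))
        assert train.n_spikes == 0

    def test_recovers_injected_spikes(self):
        dt = 1e-4
        t = np.arange(0, 2, dt)
        v = np.full_like(t, -65.0)
        truth = np.arange(0.1, 1.1, 0.1)
        for ts in truth:
            i = int(ts / dt)
            v[i:i + 20] = 20.0  # 2 ms square spike
        train = detect_spikes(t, v)
        assert train.n_spikes == 10
        assert np.allclose(train.times, truth, atol=dt * 1.5)

    def test_refinement_with_sampling_rate(self):
        f = lambda tt: -60 + 50 * np.sin(2 * np.pi * 2.0 * tt)  # 2 Hz
        t1 = np.arange(0, 2, 1e-3)
        t2 = np.arange(0, 2, 5e-4)
        d1 = detect_spikes(t1, f(t1), refractory=0.1)
        d2 = detect_spikes(t2, f(t2), refractory=0.1)
        assert d1.n_spikes == d2.n_spikes
        assert np.all(np.abs(d1.times - d2.times) < 1e-3)

    def test_nonuniform_grid_rejected(self):
        t = np.array([0.0, 0.1, 0.3, 0.35])
        with pytest.raises(InvalidParameterError):
            detect_spikes(t, np.zeros_like(t))


class TestInputResistance:
    def test_recovers_printed_means(self):
        for r in (12.03, 7.92):
            spec = PassiveTraceSpec(R=r, C=1.0, E=-60.0,
                                    pulses=[(-1.0, 1.0, 0.5)], duration=2.0,
                                    noise_sd=0.0, seed=0)
            t, v = gen_passive_trace(spec)
            est = estimate_input_resistance(t, v, -1.0, 1.0, 0.5)
            assert est == pytest.approx(r, abs=0.1)

    def test_amplitude_invariance_for_linear_membrane(self):
        ests = []
        for amp in (-1.0, -2.0):
            spec = PassiveTraceSpec(R=10.0, C=1.0, E=-60.0,
                                    pulses=[(amp, 1.0, 0.5)], duration=2.0,
                                    seed=0)
            t, v = gen_passive_trace(spec)
            ests.append(estimate_input_resistance(t, v, amp, 1.0, 0.5))
        assert ests[0] == pytest.approx(ests[1], rel=1e-6)

    def test_zero_amplitude_rejected(self):
        with pytest.raises(InvalidParameterError):
            estimate_input_resistance(np.arange(0, 2, 0.001),
                                      np.zeros(2000), 0.0, 1.0, 0.5)


class TestDeltaLeak:
    def test_equal_resistances(self):
        spec, pct = delta_leak_from_resistances(
            TempMeasurement(10.0, 8.0, -65.0), TempMeasurement(13.0, 8.0, -65.0))
        assert spec.delta_leak == 0.0 and pct == 0.0

    def test_printed_means_give_52_percent(self):
        spec, pct = delta_leak_from_resistances(
            TempMeasurement(10.0, 12.03, -65.0),
            TempMeasurement(13.0, 7.92, -68.0))
        assert spec.delta_leak == pytest.approx(43.1, abs=0.1)
        assert round(pct) == 52
        assert spec.E == -68.0

    def test_doubling_conductance(self):
        spec, pct = delta_leak_from_resistances(
            TempMeasurement(10.0, 10.0, -65.0), TempMeasurement(13.0, 5.0, -65.0))
        assert spec.delta_leak == pytest.approx(100.0)
        assert pct == pytest.approx(100.0)

    def test_cooling_warns(self):
        with pytest.warns(UserWarning):
            spec, _ = delta_leak_from_resistances(
                TempMeasurement(10.0, 5.0, -65.0), TempMeasurement(13.0, 10.0, -65.0))
        assert spec.delta_leak < 0


class TestTrendRegression:
    def test_perfect_line(self):
        x = np.linspace(8, 13, 8)
        fit = fit_temperature_trend(x, -9.81 * x + 123.48)
        assert fit.slope == pytest.approx(-9.81)
        assert fit.r_squared == pytest.approx(1.0)

    def test_degenerate_inputs(self):
        with pytest.raises(InvalidParameterError):
            fit_temperature_trend([10, 10, 10], [1, 2, 3])
        with pytest.raises(InvalidParameterError):
            fit_temperature_trend([1, 2], [1, 2])
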
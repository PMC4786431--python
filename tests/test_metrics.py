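"""Firing-rate metrics: windowed rates, kernel density, derivative peaks."""

import numpy as np
import pytest

from burstpause import (
    SpikeTrain,
    StimulusProtocol,
    frequency_change,
    max_firing_rate,
    rate_derivative,
    simulate_pulse_locked_train,
    simulate_spike_train,
    spike_density,
    time_to_max,
    total_peak_number,
    windowed_rate,
)
from burstpause.synthetic import TrainSpec

SIGMA = 25.0  # ms


def brute_force_max_rate(times, dt=0.4, step=1e-4, t_start=0.0, t_stop=None):
    """Exhaustive window placement (oracle): all sample-resolution grid
    edges plus all spike-aligned edges, counted by direct comparison."""
    if len(times) == 0:
        return 0.0
    if t_stop is None:
        t_stop = times[-1]
    edges = np.concatenate([np.arange(t_start, t_stop - dt + step, step), times])
    best = 0
    for left in edges:
        best = max(best, int(np.sum((times >= left) & (times < left + dt - 1e-12))))
    return best / dt


def regular_train(rate_hz, duration, t0=0.0, **kw):
    times = t0 + np.arange(int(round(rate_hz * duration))) / rate_hz
    return SpikeTrain(times, t_start=0.0, t_stop=max(t0 + duration, times[-1]), **kw)


class TestWindowedRate:
    def test_empty_train_rate_zero(self):
        train = SpikeTrain([], t_start=0.0, t_stop=2.0)
        assert not windowed_rate(train).rate.any()
        assert max_firing_rate(train) == 0.0

    def test_regular_100hz_max_is_100(self):
        assert max_firing_rate(regular_train(100.0, 1.0)) == pytest.approx(100.0)

    def test_known_train_brute_force_value(self):
        """Spikes at 0, 50, 100, 390, 600 ms with a 400 ms window: the best
        placement captures four spikes -> 10 Hz."""
        train = SpikeTrain(np.array([0.0, 0.05, 0.1, 0.39, 0.6]), t_start=0.0, t_stop=1.0)
        assert max_firing_rate(train) == pytest.approx(10.0)

    def test_matches_exhaustive_placement_on_random_trains(self, rng):
        for _ in range(25):
            n = int(rng.integers(1, 30))
            times = np.sort(rng.random(n) * 1.5)
            times = times[np.concatenate([[True], np.diff(times) > 1e-6])]
            train = SpikeTrain(times, t_start=0.0, t_stop=2.0)
            assert max_firing_rate(train) == pytest.approx(
                brute_force_max_rate(times, t_stop=2.0), abs=1e-9
            )

    def test_nonoverlapping_bins_mode(self):
        # spikes offset half an ISI so none sits on a bin edge
        times = 0.005 + np.arange(100) / 100.0
        train = SpikeTrain(times, t_start=0.0, t_stop=1.01)
        curve = windowed_rate(train, dt_ms=50.0, step_ms=50.0, anchor=0.0)
        assert np.all(curve.rate[:19] == pytest.approx(100.0))


class TestTimeToMax:
    def test_burst_at_onset_gives_zero(self, ir_protocol):
        t0 = ir_protocol.onset
        train = regular_train(100.0, 0.5, t0=t0, protocol=ir_protocol)
        assert time_to_max(train) == pytest.approx(0.0, abs=1e-6)

    def test_delayed_burst_gives_burst_latency(self, ir_protocol):
        """A burst starting 650 ms after onset (the slow thermoTRP-mutant
        phenotype) puts the earliest maximal window at ~650 ms."""
        t0 = ir_protocol.onset + 0.65
        train = regular_train(100.0, 0.35, t0=t0, protocol=ir_protocol)
        assert time_to_max(train) == pytest.approx(650.0, abs=1e-6)

    def test_tie_resolved_to_earliest_window(self):
        proto = StimulusProtocol("IR", onset=0.0, duration=1.0)
        train = SpikeTrain([0.1, 0.7], protocol=proto, t_start=0.0, t_stop=1.2)
        # both window placements hold one spike; the earlier one is reported
        assert time_to_max(train) == pytest.approx(100.0, abs=1e-6)

    def test_empty_train_is_signalled(self):
        train = SpikeTrain([], t_start=0.0, t_stop=1.0)
        with pytest.raises(ValueError):
            time_to_max(train, stim_onset=0.0)


class TestSpikeDensity:
    def test_single_spike_peak_value_closed_form(self):
        train = SpikeTrain([0.5], t_start=0.0, t_stop=1.0)
        curve = spike_density(train, sigma_ms=SIGMA)
        expected_peak = 1.0 / (0.025 * np.sqrt(2 * np.pi))
        assert curve.rate.max() == pytest.approx(expected_peak, rel=1e-6)
        assert curve.t[np.argmax(curve.rate)] == pytest.approx(0.5, abs=1e-4)

    def test_integral_equals_spike_count(self, rng):
        times = np.sort(rng.random(37)) * 2.0
        times = times[np.concatenate([[True], np.diff(times) > 1e-6])]
        train = SpikeTrain(times, t_start=0.0, t_stop=2.5)
        curve = spike_density(train, sigma_ms=SIGMA)
        assert curve.integral() == pytest.approx(len(train), rel=1e-3)

    def test_two_close_spikes_match_analytic_sum(self):
        t1, t2 = 0.500, 0.510
        train = SpikeTrain([t1, t2], t_start=0.0, t_stop=1.0)
        curve = spike_density(train, sigma_ms=SIGMA)
        s = 0.025
        expected = sum(
            np.exp(-0.5 * ((curve.t - tc) / s) ** 2) / (s * np.sqrt(2 * np.pi))
            for tc in (t1, t2)
        )
        np.testing.assert_allclose(curve.rate, expected, atol=1e-9)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            spike_density(SpikeTrain([0.1], t_stop=1.0), sigma_ms=0.0)


class TestRateDerivative:
    def test_constant_curve_zero_derivative(self):
        from burstpause.metrics import RateCurve

        curve = RateCurve(np.linspace(0, 1, 1001), np.full(1001, 5.0), "rect_window", 400)
        assert np.allclose(rate_derivative(curve).rate, 0.0)

    def test_linear_ramp_constant_derivative(self):
        from burstpause.metrics import RateCurve

        t = np.linspace(0, 1, 1001)
        curve = RateCurve(t, 3.0 * t, "rect_window", 400)
        assert np.allclose(rate_derivative(curve).rate, 3.0)

    def test_gaussian_density_derivative_closed_form(self):
        train = SpikeTrain([0.5], t_start=0.0, t_stop=1.0)
        deriv = rate_derivative(spike_density(train, sigma_ms=SIGMA))
        s = 0.025
        x = deriv.t - 0.5
        expected = -x / s**2 * np.exp(-0.5 * (x / s) ** 2) / (s * np.sqrt(2 * np.pi))
        np.testing.assert_allclose(deriv.rate, expected, atol=1e-3 * np.abs(expected).max())


class TestTotalPeakNumber:
    @staticmethod
    def k_burst_train(k, proto=None):
        """k well-separated regular bursts inside a 1 s stimulation window."""
        if proto is None:
            proto = StimulusProtocol("IR", onset=2.0, duration=1.0)
        w0, w1 = proto.window
        spacing = (w1 - w0) / k
        times = []
        for j in range(k):
            start = w0 + j * spacing + 0.35 * spacing
            times.extend(start + np.arange(5) * 0.01)
        return SpikeTrain(np.asarray(times), proto)

    def test_single_burst_counts_one(self):
        assert total_peak_number(self.k_burst_train(1)).total_peak_number == 1

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5, 6])
    def test_k_bursts_count_k(self, k):
        assert total_peak_number(self.k_burst_train(k)).total_peak_number == k

    def test_pulse_locked_five_cycle_protocol_counts_five(self, pulsed_protocol):
        for seed in range(5):
            train = simulate_pulse_locked_train(pulsed_protocol, seed=seed)
            assert total_peak_number(train).total_peak_number == 5

    def test_empty_window_counts_zero(self, ir_protocol):
        train = SpikeTrain([0.1], protocol=ir_protocol, t_start=0.0, t_stop=4.0)
        assert total_peak_number(train).total_peak_number == 0

    def test_invariant_under_time_translation(self):
        train = self.k_burst_train(3)
        shifted = train.shifted(1.7)
        assert (
            total_peak_number(shifted).total_peak_number
            == total_peak_number(train).total_peak_number
        )

    def test_peaks_exceed_half_primal_and_lie_in_window(self):
        train = self.k_burst_train(4)
        pk = total_peak_number(train)
        w0, w1 = train.protocol.window
        assert np.all(pk.peak_values > pk.threshold)
        assert pk.threshold == pytest.approx(0.5 * pk.primal_peak)
        assert np.all((pk.peak_times >= w0) & (pk.peak_times <= w1))


class TestFrequencyChange:
    def test_identical_rates_give_zero(self):
        train = regular_train(10.0, 10.0)
        assert frequency_change(train, stim_onset=5.0) == pytest.approx(0.0)

    def test_silent_pre_10hz_during_gives_plus_10(self):
        times = 5.0 + np.arange(50) * 0.1
        train = SpikeTrain(times, t_start=0.0, t_stop=10.0)
        assert frequency_change(train, stim_onset=5.0) == pytest.approx(10.0)

    def test_poisson_rates_recovered_on_average(self, ir_protocol):
        """5 Hz baseline vs 30 Hz evoked: mean change over 100 reps ~ 25 Hz."""
        proto = StimulusProtocol("light_continuous", onset=5.0, duration=5.0)
        changes = [
            frequency_change(
                simulate_spike_train(
                    TrainSpec(baseline_rate=5.0, evoked_rate=30.0, seed=s),
                    proto,
                    t_stop=10.0,
                )
            )
            for s in range(100)
        ]
        sem = np.sqrt((30.0 + 5.0) / 5.0 / 100)
        assert np.mean(changes) == pytest.approx(25.0, abs=3 * sem)

    def test_windows_must_fit_recording(self):
        train = regular_train(10.0, 3.0)
        with pytest.raises(ValueError):
            frequency_change(train, stim_onset=1.0)
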
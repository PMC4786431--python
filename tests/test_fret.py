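"""Ratiometric imaging pipeline: mask, ratio traces, dR_peak, transients."""

import numpy as np
import pytest
from scipy.stats import beta

from burstpause import (
    ImageStackPair,
    RatioTrace,
    StimulusProtocol,
    bleach_baseline,
    build_mask,
    classify_transient,
    dr_peak,
    extract_ratio_trace,
    occurrence_rate,
    simulate_fret_stack,
)
from burstpause.fret import DR_PEAK_WINDOW
from burstpause.synthetic import FretStackSpec

STIM = StimulusProtocol("IR", onset=2.0, duration=1.0, power=38.0)


def rect_pair(n_frames=10, shape=(32, 32), fg=200.0, bg=5.0):
    """Constant bright rectangle on a dim background."""
    cfp = np.full((n_frames, *shape), bg)
    yfp = np.full((n_frames, *shape), bg)
    cfp[:, 8:20, 10:24] = fg
    yfp[:, 8:20, 10:24] = fg
    t = np.arange(n_frames) * 0.1
    return ImageStackPair(cfp, yfp, t)


class TestBuildMask:
    def test_bright_rectangle_recovered(self):
        mask = build_mask(rect_pair(), background_radius=15)
        expected = np.zeros((32, 32), dtype=bool)
        expected[8:20, 10:24] = True
        np.testing.assert_array_equal(mask.mask, expected)

    def test_all_zero_stack_rejected(self):
        pair = ImageStackPair(np.zeros((5, 16, 16)), np.zeros((5, 16, 16)), np.arange(5) * 0.1)
        with pytest.raises(ValueError, match="all-zero"):
            build_mask(pair)

    def test_uniform_image_degenerate(self):
        pair = ImageStackPair(
            np.full((5, 16, 16), 7.0), np.full((5, 16, 16), 7.0), np.arange(5) * 0.1
        )
        with pytest.raises(ValueError, match="degenerate"):
            build_mask(pair)

    def test_single_frame_rejected(self):
        pair = ImageStackPair(np.ones((1, 8, 8)), np.ones((1, 8, 8)), np.zeros(1))
        with pytest.raises(ValueError, match="two frames"):
            build_mask(pair)

    def test_recovers_arbor_at_moderate_noise(self):
        """SNR >= 5 stack: >= 95% of true arbor pixels recovered, <= 2%
        background false positives."""
        spec = FretStackSpec(noise_sd=20.0, seed=3)  # baseline 100 -> SNR 5
        sim = simulate_fret_stack(spec, STIM)
        mask = build_mask(sim.pair)
        truth = sim.mask
        recovered = (mask.mask & truth).sum() / truth.sum()
        fp = (mask.mask & ~truth).sum() / (~truth).sum()
        assert recovered >= 0.95
        assert fp <= 0.02


class TestExtractRatioTrace:
    @staticmethod
    def sim(amplitude, noise=0.0, seed=0, **kw):
        spec = FretStackSpec(
            transient_amplitude_pct=amplitude, noise_sd=noise, seed=seed,
            shape=(48, 48), n_frames=45, **kw,
        )
        return simulate_fret_stack(spec, STIM)

    @staticmethod
    def roi_for(mask):
        rows, cols = np.nonzero(mask)
        r0 = int(rows.min())
        return (r0, r0 + 12, 0, 48)

    def test_constant_channels_give_zero_trace(self):
        sim = self.sim(0.0)
        mask = build_mask(sim.pair)
        trace = extract_ratio_trace(
            sim.pair, self.roi_for(mask.mask), mask, STIM.onset, STIM.window[1]
        )
        np.testing.assert_allclose(trace.dr, 0.0, atol=1e-9)

    def test_injected_step_recovered(self):
        sim = self.sim(30.0)
        mask = build_mask(sim.pair)
        trace = extract_ratio_trace(
            sim.pair, self.roi_for(mask.mask), mask, STIM.onset, STIM.window[1]
        )
        assert dr_peak(trace) == pytest.approx(30.0, abs=1e-6)

    def test_background_only_roi_rejected(self):
        sim = self.sim(10.0)
        mask = build_mask(sim.pair)
        empty_rows = np.nonzero(~mask.mask.any(axis=1))[0]
        roi = (int(empty_rows[0]), int(empty_rows[0]) + 1, 0, 48)
        with pytest.raises(ValueError, match="does not overlap"):
            extract_ratio_trace(sim.pair, roi, mask, STIM.onset, STIM.window[1])

    def test_ratio_invariant_to_common_channel_scaling(self):
        sim = self.sim(15.0)
        mask = build_mask(sim.pair)
        roi = self.roi_for(mask.mask)
        t1 = extract_ratio_trace(sim.pair, roi, mask, STIM.onset, STIM.window[1])
        scaled = ImageStackPair(sim.pair.cfp * 3.7, sim.pair.yfp * 3.7, sim.pair.frame_times)
        t2 = extract_ratio_trace(scaled, roi, mask, STIM.onset, STIM.window[1])
        np.testing.assert_allclose(t1.dr, t2.dr, atol=1e-9)

    def test_nonpositive_denominator_flagged(self):
        sim = self.sim(0.0)
        mask = build_mask(sim.pair)
        cfp = sim.pair.cfp.copy()
        cfp[5] = 0.0  # kill the donor signal in one frame
        pair = ImageStackPair(cfp, sim.pair.yfp, sim.pair.frame_times)
        trace = extract_ratio_trace(
            pair, self.roi_for(mask.mask), mask, STIM.onset, STIM.window[1]
        )
        assert 5 in trace.flagged
        assert np.isnan(trace.dr[5])


class TestDrPeak:
    def test_flat_zero_trace(self):
        t = np.arange(0, 5, 0.1)
        assert dr_peak(RatioTrace(t, np.zeros(t.size), stim_end=3.0)) == 0.0

    def test_constant_plateau(self):
        t = np.arange(0, 5, 0.1)
        assert dr_peak(RatioTrace(t, np.full(t.size, 20.0), stim_end=3.0)) == pytest.approx(20.0)

    def test_exponential_decay_window_average_closed_form(self):
        t = np.arange(0, 6, 0.1)
        tau, amp, t0 = 1.5, 40.0, 3.0
        dr = np.where(t >= t0, amp * np.exp(-(t - t0) / tau), 0.0)
        lo, hi = t0 + DR_PEAK_WINDOW[0], t0 + DR_PEAK_WINDOW[1]
        frames = t[(t >= lo - 1e-9) & (t <= hi + 1e-9)]
        expected = amp * np.exp(-(frames - t0) / tau).mean()
        assert dr_peak(RatioTrace(t, dr, stim_end=t0)) == pytest.approx(expected)

    def test_insufficient_coverage_rejected(self):
        t = np.arange(0, 3.2, 0.1)
        with pytest.raises(ValueError, match="cover"):
            dr_peak(RatioTrace(t, np.zeros(t.size), stim_end=3.0))


class TestClassification:
    @pytest.mark.parametrize("value,expected", [(12.0, True), (8.0, False), (10.0, False)])
    def test_threshold_is_strict(self, value, expected):
        assert classify_transient(value) is expected

    def test_occurrence_rates_known_counts(self):
        """13 of 18 transients -> 72.2%; 0 of 9 -> 0% with a zero lower bound."""
        rate, _ = occurrence_rate([True] * 13 + [False] * 5)
        assert rate == pytest.approx(72.2, abs=0.05)
        rate0, (lo, hi) = occurrence_rate([False] * 9)
        assert rate0 == 0.0
        assert lo == 0.0

    def test_interval_matches_beta_quantile_oracle(self):
        k, n, alpha = 13, 18, 0.05
        _, (lo, hi) = occurrence_rate([True] * k + [False] * (n - k))
        assert lo / 100 == pytest.approx(beta.ppf(alpha / 2, k, n - k + 1), abs=1e-9)
        assert hi / 100 == pytest.approx(beta.ppf(1 - alpha / 2, k + 1, n - k), abs=1e-9)

    def test_interval_contains_point_estimate(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 40))
            k = int(rng.integers(0, n + 1))
            p, (lo, hi) = occurrence_rate([True] * k + [False] * (n - k))
            assert lo - 1e-9 <= p <= hi + 1e-9

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            occurrence_rate([])


class TestBleachBaseline:
    def test_constant_trace_zero_decay(self):
        t = np.arange(0, 10, 0.1)
        fit = bleach_baseline(t, np.full(t.size, 50.0))
        assert fit.rate == 0.0
        assert np.allclose(fit.residuals, 0.0)

    def test_noiseless_exponential_recovered_exactly(self):
        t = np.arange(0, 20, 0.1)
        f = 30.0 + 70.0 * np.exp(-0.08 * t)
        fit = bleach_baseline(t, f)
        assert fit.converged
        assert fit.amplitude == pytest.approx(70.0, rel=1e-6)
        assert fit.rate == pytest.approx(0.08, rel=1e-6)
        assert fit.offset == pytest.approx(30.0, rel=1e-6)

    def test_irradiation_dips_excluded_from_fit(self):
        """Heat-dependent fluorescence dips during irradiation must not bias
        the bleaching curve; the signal recovers to the fitted level."""
        t = np.arange(0, 20, 0.1)
        f = 30.0 + 70.0 * np.exp(-0.08 * t)
        windows = [(5.0, 6.0), (12.0, 13.0)]
        dipped = f.copy()
        for w0, w1 in windows:
            dipped[(t >= w0) & (t <= w1)] -= 25.0
        fit = bleach_baseline(t, dipped, windows)
        assert fit.rate == pytest.approx(0.08, rel=1e-6)
        outside = np.ones(t.size, bool)
        for w0, w1 in windows:
            outside &= ~((t >= w0) & (t <= w1))
        assert np.allclose(fit.residuals[outside], 0.0, atol=1e-6)
        assert np.all(fit.residuals[~outside] < -20.0)
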
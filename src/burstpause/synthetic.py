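"""Synthetic inputs with the statistical structure of larval nociceptor trials.

Every generator here is a pure function of its parameters and seed, and
emits its ground truth alongside the simulated object so that each
downstream analysis stage has an oracle:

* inhomogeneous Poisson spike trains with optional embedded burst-pause
  (unconventional-spike) triplets, at baseline rates outside the stimulus
  and evoked rates inside it (on-phases only for pulsed drive);
* extracellular voltage traces built from a biphasic spike template plus
  Gaussian noise;
* two-channel FRET stacks in which a Ca2+ transient raises YFP and
  lowers CFP simultaneously across a dendritic arbor mask and decays
  monoexponentially, with slower soma kinetics;
* electrode-resistance calibration pairs obeying the Arrhenius law;
* coupled spike-train / ratio-trace trials whose Ca2+ amplitude grows
  with the number of embedded burst-pause events.

Firing statistics are phenomenological: no channel gating is modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ImageStackPair, RatioTrace, SpikeTrain, StimulusProtocol, VoltageTrace
from .fret import DR_PEAK_WINDOW

__all__ = [
    "TrainSpec",
    "FretStackSpec",
    "SimulatedFret",
    "simulate_spike_train",
    "simulate_pulse_locked_train",
    "biphasic_template",
    "simulate_voltage_trace",
    "make_arbor_skeleton",
    "simulate_fret_stack",
    "simulate_calibration_data",
    "simulate_coupled_trial",
    "ARRHENIUS_A",
    "ARRHENIUS_B",
]

# Plausible glass-microelectrode calibration: ~7 MOhm at 25 degC falling
# to ~5 MOhm at 50 degC.
ARRHENIUS_A = 1.852e-3
ARRHENIUS_B = 7.73e-4


@dataclass(frozen=True)
class TrainSpec:
    """Parameters of one simulated spike train.

    ``evoked_rate`` defaults to the mean maximum firing rate of strongly
    heat-driven wild-type neurons (~84 Hz); ``us_events`` embeds that many
    burst-pause triplets (first ISI ``us_isi1_ms`` < 9 ms, second ISI
    > 20 ms) in the stimulus window, each followed by a silent pause of
    ``pause_duration_ms``. The pause doubles as the triplet's second
    interval, so it is floored at 25 ms whenever triplets are injected.
    ``post_pause_depression`` optionally thins the firing rate by that
    fraction for ``depression_ms`` after each pause (off by default; the
    duration of the physiological rate depression is a free parameter).
    """

    baseline_rate: float = 2.0
    evoked_rate: float = 84.0
    us_events: int = 0
    pause_duration_ms: float = 100.0
    seed: int = 0
    us_isi1_ms: float = 5.0
    post_pause_depression: float = 0.0
    depression_ms: float = 200.0
    evoked_mode: str = "poisson"
    evoked_jitter_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.evoked_rate < 0:
            raise ValueError("firing rates must be nonnegative")
        if self.pause_duration_ms < 0:
            raise ValueError("pause duration must be nonnegative")
        if not 0 <= self.post_pause_depression <= 1:
            raise ValueError("depression must be a fraction in [0, 1]")
        if not 0 < self.us_isi1_ms < 9.0:
            raise ValueError("first US interval must be in (0, 9) ms")
        if self.evoked_mode not in ("poisson", "regular"):
            raise ValueError("evoked_mode must be 'poisson' or 'regular'")


def _piecewise_poisson(rng, intervals) -> np.ndarray:
    """Sample an inhomogeneous Poisson train with piecewise-constant rate."""
    times = []
    for t0, t1, rate in intervals:
        span = t1 - t0
        if span <= 0 or rate <= 0:
            continue
        n = rng.poisson(rate * span)
        if n:
            times.append(t0 + rng.random(n) * span)
    if not times:
        return np.array([])
    return np.sort(np.concatenate(times))


def simulate_spike_train(
    spec: TrainSpec,
    protocol: StimulusProtocol,
    t_start: float = 0.0,
    t_stop: float | None = None,
    trial_id: str = "",
) -> SpikeTrain:
    """Simulate one trial's spike train under a stimulus protocol.

    Firing is inhomogeneous Poisson: ``baseline_rate`` outside the
    stimulus window and ``evoked_rate`` inside it (during on-phases only
    for pulsed protocols, with baseline firing in the off-phases). US
    triplets are then injected at evenly spaced anchors across the
    stimulus window, replacing background spikes locally so the injected
    ISI pattern is guaranteed to satisfy the detector's definition.
    """
    if t_stop is None:
        t_stop = protocol.window[1] + 1.0
    rng = np.random.default_rng(spec.seed)

    on = protocol.on_intervals()
    intervals = []
    evoked_spans = []
    prev = t_start
    for a, b in on:
        if a > prev:
            intervals.append((prev, a, spec.baseline_rate))
        span = (max(a, t_start), min(b, t_stop))
        if spec.evoked_mode == "poisson":
            intervals.append((*span, spec.evoked_rate))
        else:
            evoked_spans.append(span)
        prev = b
    if prev < t_stop:
        intervals.append((prev, t_stop, spec.baseline_rate))
    times = _piecewise_poisson(rng, intervals)
    if evoked_spans and spec.evoked_rate > 0:
        # tonic quasi-regular firing: refractoriness makes sustained
        # high-frequency trains far more regular than a Poisson process
        period = 1.0 / spec.evoked_rate
        reg = []
        for a, b in evoked_spans:
            t = a + rng.random() * period
            while t < b:
                reg.append(t + rng.normal(0.0, spec.evoked_jitter_ms / 1000.0))
                t += period
        times = np.sort(np.concatenate([times, np.asarray(reg)]))

    if spec.us_events > 0:
        isi1 = spec.us_isi1_ms / 1000.0
        gap = max(spec.pause_duration_ms, 25.0) / 1000.0
        w0, w1 = protocol.window
        spacing = (w1 - w0) / (spec.us_events + 1)
        if spacing <= isi1 + gap + 0.01:
            raise ValueError("too many US events for the stimulus window")
        silenced = []
        injected = []
        # guards keep any background spike further from the injected
        # triplet than the US interval itself, so the trial's shortest
        # ISI lies inside a US
        guard = (spec.us_isi1_ms + 1.0) / 1000.0
        for j in range(spec.us_events):
            s1 = w0 + (j + 1) * spacing
            s2 = s1 + isi1
            s3 = s2 + gap
            injected.extend([s1, s2, s3])
            silenced.append((s1 - guard, s3 + guard))
        keep = np.ones(times.size, dtype=bool)
        for a, b in silenced:
            keep &= ~((times >= a) & (times <= b))
        times = np.sort(np.concatenate([times[keep], np.asarray(injected)]))
        if spec.post_pause_depression > 0:
            dep = spec.depression_ms / 1000.0
            u = rng.random(times.size)
            keep = np.ones(times.size, dtype=bool)
            for j in range(spec.us_events):
                end = w0 + (j + 1) * spacing + isi1 + gap
                in_dep = (times > end) & (times <= end + dep)
                drop = in_dep & (u < spec.post_pause_depression)
                drop &= ~np.isclose(times, end)  # keep the injected third spike
                keep &= ~drop
            times = times[keep]

    # Guard against coincident samples (measure zero, but be strict).
    if times.size > 1:
        times = times[np.concatenate([[True], np.diff(times) > 0])]
    return SpikeTrain(times, protocol, trial_id, t_start, t_stop)


def simulate_pulse_locked_train(
    protocol: StimulusProtocol,
    burst_rate: float = 100.0,
    latency_ms: float = 25.0,
    jitter_ms: float = 2.0,
    baseline_rate: float = 0.0,
    seed: int = 0,
    t_start: float = 0.0,
    t_stop: float | None = None,
    trial_id: str = "",
) -> SpikeTrain:
    """Simulate reliably pulse-locked firing under square-pulse drive.

    Direct strong optogenetic activation (channelrhodopsin-family
    actuators at ~100 ms pulses) drives near-deterministic spiking: after
    an onset latency, the neuron fires regularly at ``burst_rate`` for
    the rest of each on-phase, with small Gaussian timing jitter. This is
    the appropriate emulation of intermittent-activation recordings,
    whose per-pulse burst reliability a Poisson model understates; the
    defaults (100 Hz within bursts, 25 ms latency at the low irradiances
    used behaviourally, 2 ms jitter) put the sliding-window maximum
    firing rate of the 100 ms on / 100 ms off protocol in the low-40 Hz
    range. Off-phases carry optional Poisson baseline firing.
    """
    if burst_rate <= 0:
        raise ValueError("burst rate must be positive")
    if t_stop is None:
        t_stop = protocol.window[1] + 1.0
    rng = np.random.default_rng(seed)
    times = []
    on = protocol.on_intervals()
    for a, b in on:
        t = a + latency_ms / 1000.0
        while t < b:
            times.append(t + rng.normal(0.0, jitter_ms / 1000.0))
            t += 1.0 / burst_rate
    if baseline_rate > 0:
        gaps = []
        prev = t_start
        for a, b in on:
            if a > prev:
                gaps.append((prev, a, baseline_rate))
            prev = b
        if prev < t_stop:
            gaps.append((prev, t_stop, baseline_rate))
        times.extend(_piecewise_poisson(rng, gaps).tolist())
    times = np.sort(np.asarray(times))
    times = times[(times >= t_start) & (times <= t_stop)]
    if times.size > 1:
        times = times[np.concatenate([[True], np.diff(times) > 0])]
    return SpikeTrain(times, protocol, trial_id, t_start, t_stop)


def biphasic_template(fs: float, duration_ms: float = 2.0, amplitude: float = 1.0) -> np.ndarray:
    """One cycle of a sine: positive lobe then negative lobe, zero ends."""
    n = max(4, int(round(duration_ms * 1e-3 * fs)))
    t = np.arange(n) / n
    return amplitude * np.sin(2.0 * np.pi * t)


def simulate_voltage_trace(
    train: SpikeTrain,
    waveform: np.ndarray | None = None,
    noise_sd: float = 0.0,
    fs: float = 10_000.0,
    seed: int = 0,
) -> tuple[VoltageTrace, np.ndarray]:
    """Superpose a biphasic template at each spike time plus Gaussian noise.

    The template's positive peak is aligned to the spike time (quantised
    to the sample grid); returns the trace and the ground-truth aligned
    peak times. Spikes spaced more closely than the template support are
    flagged with a warning (overlapping waveforms), not an error.
    """
    if fs not in (10_000.0, 20_000.0):
        raise ValueError("sampling rate must be 10 or 20 kHz")
    if waveform is None:
        waveform = biphasic_template(fs)
    waveform = np.asarray(waveform, dtype=float)
    peak_off = int(np.argmax(waveform))

    n = int(np.ceil((train.t_stop - train.t_start) * fs)) + 1
    rng = np.random.default_rng(seed)
    samples = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    truth = []
    for t in train.times:
        i_peak = int(round((t - train.t_start) * fs))
        start = i_peak - peak_off
        lo = max(start, 0)
        hi = min(start + waveform.size, n)
        if hi <= lo:
            continue
        samples[lo:hi] += waveform[lo - start : hi - start]
        truth.append(train.t_start + i_peak / fs)
    if train.times.size > 1:
        support = waveform.size / fs
        if np.any(np.diff(train.times) < support):
            warnings.warn("spike spacing shorter than template support; waveforms overlap",
                          stacklevel=2)
    return VoltageTrace(samples, fs, train.t_start), np.asarray(truth)


def make_arbor_skeleton(
    shape: tuple[int, int], n_branches: int = 6, seed: int = 0
) -> np.ndarray:
    """Random-walk dendritic arbor skeleton radiating from the image centre."""
    rng = np.random.default_rng(seed)
    h, w = shape
    skel = np.zeros(shape, dtype=bool)
    cy, cx = h // 2, w // 2
    for b in range(n_branches):
        angle = 2.0 * np.pi * b / n_branches + rng.normal(0, 0.2)
        y, x = float(cy), float(cx)
        steps = int(0.45 * min(h, w))
        for _ in range(steps):
            angle += rng.normal(0, 0.25)
            y += np.sin(angle)
            x += np.cos(angle)
            iy, ix = int(round(y)), int(round(x))
            if not (1 <= iy < h - 1 and 1 <= ix < w - 1):
                break
            skel[iy, ix] = True
    skel[cy, cx] = True
    return skel


@dataclass(frozen=True)
class FretStackSpec:
    """Parameters of a simulated two-channel FRET recording.

    ``transient_amplitude_pct`` is parameterised on the ratio, not the
    channels: it is the trial's representative amplitude, i.e. the mean
    dR/R0 over the post-stimulus averaging window, in percent. The
    transient rises simultaneously at all arbor pixels during the
    stimulus and decays monoexponentially with ``decay_tau``; flagged
    soma pixels follow slower kinetics with ``soma_tau``.
    """

    shape: tuple[int, int] = (64, 64)
    n_frames: int = 60
    frame_interval: float = 0.1
    arbor_skeleton: np.ndarray | None = None
    baseline_cfp: float = 100.0
    baseline_yfp: float = 100.0
    background_level: float = 10.0
    transient_amplitude_pct: float = 30.0
    decay_tau: float = 2.0
    soma_tau: float = 6.0
    soma_radius: int = 0  # 0: no soma region
    noise_sd: float = 0.0
    bleach_rate: float = 0.0
    dilation_radius: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.transient_amplitude_pct < 0:
            raise ValueError("transient amplitude must be nonnegative")
        if self.decay_tau <= 0 or self.soma_tau <= 0:
            raise ValueError("decay constants must be positive")


@dataclass(frozen=True)
class SimulatedFret:
    """A simulated recording plus its ground truth."""

    pair: ImageStackPair
    mask: np.ndarray  # ground-truth arbor mask (dilated skeleton)
    soma_mask: np.ndarray
    truth: RatioTrace  # ground-truth dendritic dR/R0 trace (%)
    amplitude_pct: float


def _window_weight(frame_times: np.ndarray, stim_end: float, tau: float) -> float:
    """Mean of the exponential decay over the frames inside the
    post-stimulus averaging window (the pipeline's dR_peak frames)."""
    lo = stim_end + DR_PEAK_WINDOW[0]
    hi = stim_end + DR_PEAK_WINDOW[1]
    sel = (frame_times >= lo - 1e-9) & (frame_times <= hi + 1e-9)
    if not sel.any():
        raise ValueError("stack does not cover the post-stimulus averaging window")
    return float(np.exp(-(frame_times[sel] - stim_end) / tau).mean())


def _transient_profile(
    t: np.ndarray, onset: float, end: float, peak: float, tau: float
) -> np.ndarray:
    """Fractional ratio modulation: linear rise to ``peak`` during the
    stimulus, monoexponential decay afterwards."""
    g = np.zeros_like(t)
    rise = (t >= onset) & (t < end)
    g[rise] = peak * (t[rise] - onset) / max(end - onset, 1e-9)
    after = t >= end
    g[after] = peak * np.exp(-(t[after] - end) / tau)
    return g


def simulate_fret_stack(
    spec: FretStackSpec, protocol: StimulusProtocol
) -> SimulatedFret:
    """Simulate a co-registered CFP/YFP stack with a dendritic transient.

    A FRET increase raises YFP and lowers CFP anti-symmetrically so the
    YFP/CFP ratio change equals the prescribed transient while total
    brightness stays near baseline. Photobleaching multiplies both
    fluorophores equally and therefore cancels in the ratio. Pixel noise
    is Gaussian, clipped at zero.
    """
    from skimage.morphology import dilation, disk

    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    skel = spec.arbor_skeleton
    if skel is None:
        skel = make_arbor_skeleton((h, w), seed=spec.seed)
    skel = np.asarray(skel, dtype=bool)
    if not skel.any():
        raise ValueError("arbor skeleton is empty")
    mask = dilation(skel, disk(spec.dilation_radius))

    soma = np.zeros((h, w), dtype=bool)
    if spec.soma_radius > 0:
        yy, xx = np.ogrid[:h, :w]
        soma = (yy - h // 2) ** 2 + (xx - w // 2) ** 2 <= spec.soma_radius**2
        mask = mask | soma

    t = np.arange(spec.n_frames) * spec.frame_interval
    onset, end = protocol.window

    if spec.transient_amplitude_pct > 0:
        wgt = _window_weight(t, end, spec.decay_tau)
        peak_frac = spec.transient_amplitude_pct / 100.0 / wgt
    else:
        peak_frac = 0.0
    g_dend = _transient_profile(t, onset, end, peak_frac, spec.decay_tau)
    g_soma = _transient_profile(t, onset, end, peak_frac, spec.soma_tau)
    # slow rise in the soma as well: first-order relaxation toward the peak
    rise = (t >= onset) & (t < end)
    if spec.soma_radius > 0 and rise.any():
        g_soma[rise] = peak_frac * (1.0 - np.exp(-(t[rise] - onset) / spec.soma_tau))

    bleach = np.exp(-spec.bleach_rate * t)
    dend_only = mask & ~soma

    cfp = np.full((spec.n_frames, h, w), spec.background_level, dtype=float)
    yfp = np.full((spec.n_frames, h, w), spec.background_level, dtype=float)
    for region, g in ((dend_only, g_dend), (soma, g_soma)):
        if not region.any():
            continue
        up = np.sqrt(1.0 + g)
        cfp[:, region] += (spec.baseline_cfp * bleach / up)[:, None]
        yfp[:, region] += (spec.baseline_yfp * bleach * up)[:, None]

    if spec.noise_sd > 0:
        cfp = np.clip(cfp + rng.normal(0, spec.noise_sd, cfp.shape), 0, None)
        yfp = np.clip(yfp + rng.normal(0, spec.noise_sd, yfp.shape), 0, None)

    pair = ImageStackPair(cfp, yfp, t)
    truth = RatioTrace(t, 100.0 * g_dend, roi_id="ground_truth", stim_end=end)
    return SimulatedFret(pair, mask, soma, truth, spec.transient_amplitude_pct)


def simulate_calibration_data(
    a: float = ARRHENIUS_A,
    b: float = ARRHENIUS_B,
    n: int = 20,
    noise_sd: float = 0.0,
    seed: int = 0,
    t_range_c: tuple[float, float] = (25.0, 50.0),
) -> np.ndarray:
    """Resistance/temperature calibration pairs obeying the Arrhenius law.

    Temperatures are evenly spread over ``t_range_c`` (a natural-cooling
    sweep); Gaussian noise of sd ``noise_sd`` is applied to the inverse
    absolute temperature, the quantity that is linear in ln(R). Returns
    an (n, 2) array of (R in MOhm, T in Celsius).
    """
    if b == 0:
        raise ValueError("slope b must be nonzero")
    if n < 2:
        raise ValueError("need at least two calibration pairs")
    if not (20.0 <= t_range_c[0] < t_range_c[1] <= 55.0):
        raise ValueError("calibration temperatures must lie within 20-55 degC")
    rng = np.random.default_rng(seed)
    t_c = np.linspace(t_range_c[0], t_range_c[1], n)
    inv_t = 1.0 / (t_c + 273.15)
    r = np.exp((inv_t - a) / b)
    inv_noisy = a + b * np.log(r) + (rng.normal(0, noise_sd, n) if noise_sd > 0 else 0.0)
    t_out = 1.0 / inv_noisy - 273.15
    return np.column_stack([r, t_out])


def simulate_coupled_trial(
    k_us: int,
    gain_pct_per_us: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    protocol: StimulusProtocol | None = None,
    decay_tau: float = 1.5,
    frame_interval: float = 0.1,
    trial_id: str = "",
) -> tuple[SpikeTrain, RatioTrace]:
    """One paired spike-train / Ca2+ trial with a known coupling.

    The spike train embeds ``k_us`` burst-pause triplets; the ratio trace
    carries a transient whose representative amplitude is
    ``gain * k_us`` percent plus Gaussian noise. Across trials with
    varying ``k_us`` the ratio amplitude therefore increases
    monotonically with the embedded US count.
    """
    if gain_pct_per_us < 0:
        raise ValueError("coupling gain must be nonnegative")
    if protocol is None:
        protocol = StimulusProtocol("IR", onset=2.0, duration=1.0, power=40.0)
    ss = np.random.SeedSequence(seed)
    s_train, s_amp = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))

    # Quasi-regular evoked firing: tonic ~84 Hz trains carry no chance
    # burst-pause triplets (their ISIs are too uniform), so the detected
    # US count tracks the injected count.
    spec = TrainSpec(us_events=k_us, seed=s_train, evoked_mode="regular")
    train = simulate_spike_train(
        spec, protocol, t_stop=protocol.window[1] + 2.0, trial_id=trial_id
    )

    onset, end = protocol.window
    t = np.arange(0.0, end + 2.0 + frame_interval / 2, frame_interval)
    amp = gain_pct_per_us * k_us
    if noise_sd > 0:
        amp += np.random.default_rng(s_amp).normal(0.0, noise_sd)
    if amp != 0:
        wgt = _window_weight(t, end, decay_tau)
        peak = amp / wgt
    else:
        peak = 0.0
    dr = 100.0 * _transient_profile(t, onset, end, peak / 100.0, decay_tau)
    trace = RatioTrace(t, dr, roi_id=trial_id, stim_end=end)
    return train, trace
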
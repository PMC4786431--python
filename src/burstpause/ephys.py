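"""Voltage-trace conditioning, spike detection, and waveform averaging.

The conditioning chain reproduces the acquisition-style band-pass used for
extracellular suction-electrode recordings of larval sensory neurons: a
first-order RC high-pass at 100 Hz followed by an 8-pole Butterworth
low-pass at 2 kHz. Spikes are then extracted by threshold crossing with a
refractory window, timestamped at the local extremum after the crossing.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal

from .core import SpikeTrain, StimulusProtocol, VoltageTrace

__all__ = ["bandpass_filter", "detect_spikes", "align_and_average"]

HIGHPASS_FC = 100.0  # Hz, RC monopole
LOWPASS_FC = 2000.0  # Hz, Butterworth 8-pole


def bandpass_cascade_gain(f, fs: float | None = None) -> np.ndarray:
    """Analytic magnitude of the band-pass cascade at frequencies ``f`` (Hz).

    |H| = |H_RC(f)| * |H_BW8(f)| for the ideal continuous-time filters.
    Provided so callers (and tests) can check the implemented digital
    cascade against the nominal transfer function.
    """
    f = np.asarray(f, dtype=float)
    h_rc = (f / HIGHPASS_FC) / np.sqrt(1.0 + (f / HIGHPASS_FC) ** 2)
    h_bw = 1.0 / np.sqrt(1.0 + (f / LOWPASS_FC) ** 16)
    return h_rc * h_bw


def bandpass_filter(trace: VoltageTrace, zero_phase: bool = False) -> VoltageTrace:
    """Apply the RC(100 Hz) high-pass + 8-pole Butterworth(2 kHz) low-pass.

    Causal (forward-only) by default, matching online acquisition; set
    ``zero_phase=True`` for offline forward-backward filtering, which
    preserves spike peak positions at the cost of non-causality.
    """
    if trace.fs <= 2 * LOWPASS_FC:
        raise ValueError(
            f"sampling rate {trace.fs} Hz too low for a {LOWPASS_FC} Hz low-pass"
        )
    # A first-order Butterworth high-pass is exactly the RC monopole.
    sos_hp = signal.butter(1, HIGHPASS_FC, btype="highpass", fs=trace.fs, output="sos")
    sos_lp = signal.butter(8, LOWPASS_FC, btype="lowpass", fs=trace.fs, output="sos")
    sos = np.vstack([sos_hp, sos_lp])
    if zero_phase:
        y = signal.sosfiltfilt(sos, trace.samples)
    else:
        y = signal.sosfilt(sos, trace.samples)
    return VoltageTrace(y, trace.fs, trace.t0)


def detect_spikes(
    trace: VoltageTrace,
    threshold: float,
    refractory_ms: float = 2.0,
    polarity: str = "pos",
    search_ms: float = 1.0,
    protocol: StimulusProtocol | None = None,
    trial_id: str = "",
) -> SpikeTrain:
    """Threshold-crossing spike detection on a (filtered) voltage trace.

    One spike is emitted per upward crossing of ``threshold`` (downward for
    ``polarity="neg"``), timestamped at the local extremum within
    ``search_ms`` after the crossing. Crossings within ``refractory_ms`` of
    the previous accepted spike are ignored, which prevents the two lobes
    of a biphasic waveform from being counted twice.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if polarity not in ("pos", "neg"):
        raise ValueError("polarity must be 'pos' or 'neg'")
    x = trace.samples if polarity == "pos" else -trace.samples
    thr = threshold if polarity == "pos" else -threshold

    above = x >= thr
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if above.size and above[0]:
        crossings = np.concatenate([[0], crossings])

    search = max(1, int(round(search_ms * 1e-3 * trace.fs)))
    refractory = refractory_ms * 1e-3
    spike_idx: list[int] = []
    last_t = -np.inf
    for c in crossings:
        seg = x[c : c + search + 1]
        peak = c + int(np.argmax(seg))
        t = trace.t0 + peak / trace.fs
        if t - last_t < refractory:
            continue
        spike_idx.append(peak)
        last_t = t
    times = trace.t0 + np.asarray(spike_idx, dtype=float) / trace.fs
    return SpikeTrain(
        times,
        protocol=protocol,
        trial_id=trial_id,
        t_start=trace.t0,
        t_stop=trace.t0 + trace.duration,
    )


def align_and_average(
    traces: list[VoltageTrace],
    anchors: list[np.ndarray],
    window_ms: tuple[float, float] = (2.0, 5.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average waveform snippets aligned at anchor times.

    ``anchors[i]`` holds the anchor times (seconds) for ``traces[i]``,
    typically spike peaks. Snippets of ``window_ms = (pre, post)`` around
    each anchor are extracted and averaged pointwise; anchors too close to
    a trace edge are dropped with a warning.

    Returns ``(lags_ms, mean, sd)`` where ``sd`` is the pointwise
    population standard deviation across snippets (zero for identical or
    single snippets).
    """
    if len(traces) != len(anchors):
        raise ValueError("one anchor array per trace is required")
    fs = traces[0].fs
    if any(tr.fs != fs for tr in traces):
        raise ValueError("all traces must share the sampling rate")
    pre = int(round(window_ms[0] * 1e-3 * fs))
    post = int(round(window_ms[1] * 1e-3 * fs))
    snippets = []
    n_dropped = 0
    for tr, anks in zip(traces, anchors):
        for t in np.atleast_1d(np.asarray(anks, dtype=float)):
            i = int(round((t - tr.t0) * fs))
            if i - pre < 0 or i + post >= tr.samples.size:
                n_dropped += 1
                continue
            snippets.append(tr.samples[i - pre : i + post + 1])
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} snippet(s) at trace edges", stacklevel=2)
    if not snippets:
        raise ValueError("no usable snippets (all anchors near trace edges?)")
    arr = np.vstack(snippets)
    lags_ms = (np.arange(-pre, post + 1) / fs) * 1000.0
    return lags_ms, arr.mean(axis=0), arr.std(axis=0, ddof=0)
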
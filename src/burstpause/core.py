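"""Shared data containers for electrophysiology and ratiometric imaging trials.

All times are seconds unless a name says otherwise; interspike intervals are
reported in milliseconds, matching the conventions of the firing-pattern
metrics built on top of these containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "StimulusProtocol",
    "SpikeTrain",
    "VoltageTrace",
    "RatioTrace",
    "ImageStackPair",
]


@dataclass(frozen=True)
class StimulusProtocol:
    """Description of one stimulation epoch.

    Parameters
    ----------
    kind:
        ``"IR"`` (focal infrared laser), ``"light_continuous"`` (steady blue
        light) or ``"light_pulsed"`` (square-pulse optogenetic drive).
    onset, duration:
        Stimulus window in seconds, on the same clock as spike times.
    power:
        Laser output in mW (IR) or irradiance in mW/mm^2 (light).
    pulse_on, pulse_off:
        On/off phase lengths in milliseconds (pulsed only).
    n_pulses:
        Number of on-phases (pulsed only).
    """

    kind: str
    onset: float
    duration: float
    power: float = 0.0
    pulse_on: float = 100.0
    pulse_off: float = 100.0
    n_pulses: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("IR", "light_continuous", "light_pulsed"):
            raise ValueError(f"unknown stimulus kind: {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.kind == "light_pulsed":
            if self.n_pulses < 1:
                raise ValueError("pulsed protocol needs n_pulses >= 1")
            if self.pulse_on <= 0 or self.pulse_off < 0:
                raise ValueError("pulse phases must be positive")
            total_ms = self.n_pulses * (self.pulse_on + self.pulse_off)
            if total_ms > self.duration * 1000.0 + self.pulse_off + 1e-9:
                raise ValueError("pulse cycles do not fit in the stimulus window")

    @property
    def window(self) -> tuple[float, float]:
        """(start, end) of the stimulation period in seconds."""
        return (self.onset, self.onset + self.duration)

    def on_intervals(self) -> list[tuple[float, float]]:
        """Intervals during which the stimulus actually drives the neuron.

        For continuous protocols this is the whole window; for pulsed
        protocols, the list of on-phases.
        """
        if self.kind != "light_pulsed":
            return [self.window]
        cycle = (self.pulse_on + self.pulse_off) / 1000.0
        on = self.pulse_on / 1000.0
        return [
            (self.onset + k * cycle, self.onset + k * cycle + on)
            for k in range(self.n_pulses)
        ]


def _as_sorted_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float).ravel()
    if t.size and not np.all(np.isfinite(t)):
        raise ValueError("spike times must be finite")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("spike times must be strictly increasing")
    return t


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one trial plus its stimulus context."""

    times: np.ndarray
    protocol: Optional[StimulusProtocol] = None
    trial_id: str = ""
    t_start: float = 0.0
    t_stop: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", _as_sorted_times(self.times))
        stop = self.t_stop
        if stop is None:
            stop = float(self.times[-1]) if self.times.size else self.t_start
            if self.protocol is not None:
                stop = max(stop, self.protocol.window[1])
            object.__setattr__(self, "t_stop", stop)
        if self.t_stop < self.t_start:
            raise ValueError("t_stop must be >= t_start")
        if self.times.size and (
            self.times[0] < self.t_start - 1e-12 or self.times[-1] > self.t_stop + 1e-12
        ):
            raise ValueError("spike times fall outside the recording extent")

    def __len__(self) -> int:
        return int(self.times.size)

    def count_in(self, t0: float, t1: float) -> int:
        """Number of spikes in the half-open interval [t0, t1)."""
        lo, hi = np.searchsorted(self.times, [t0, t1], side="left")
        return int(hi - lo)

    def isis_ms(self) -> np.ndarray:
        """Consecutive interspike intervals in milliseconds."""
        return np.diff(self.times) * 1000.0

    def shifted(self, dt: float) -> "SpikeTrain":
        """Uniform time translation of spikes, extent, and protocol."""
        proto = self.protocol
        if proto is not None:
            proto = replace(proto, onset=proto.onset + dt)
        return SpikeTrain(
            self.times + dt, proto, self.trial_id, self.t_start + dt, self.t_stop + dt
        )


@dataclass(frozen=True)
class VoltageTrace:
    """Uniformly sampled extracellular voltage."""

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float).ravel())
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("voltage samples must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class RatioTrace:
    """FRET ratio change (percent dR/R0) of one ROI over time.

    ``stim_end`` anchors the post-stimulus averaging window used to extract
    the trial's representative amplitude; ``flagged`` lists frame indices
    where the background-subtracted donor signal was non-positive and the
    ratio is unreliable.
    """

    t: np.ndarray
    dr: np.ndarray
    roi_id: str = ""
    stim_end: float = 0.0
    flagged: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float).ravel()
        dr = np.asarray(self.dr, dtype=float).ravel()
        if t.size != dr.size:
            raise ValueError("t and dr must have equal length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("frame times must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "dr", dr)


@dataclass(frozen=True)
class ImageStackPair:
    """Co-registered CFP and YFP stacks, frames first: (frame, row, col)."""

    cfp: np.ndarray
    yfp: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        cfp = np.asarray(self.cfp, dtype=float)
        yfp = np.asarray(self.yfp, dtype=float)
        ft = np.asarray(self.frame_times, dtype=float).ravel()
        if cfp.shape != yfp.shape:
            raise ValueError("CFP and YFP stacks must have identical shapes")
        if cfp.ndim != 3:
            raise ValueError("stacks must be (frame, row, col)")
        if cfp.shape[0] != ft.size:
            raise ValueError("one timestamp per frame is required")
        object.__setattr__(self, "cfp", cfp)
        object.__setattr__(self, "yfp", yfp)
        object.__setattr__(self, "frame_times", ft)

    @property
    def n_frames(self) -> int:
        return int(self.cfp.shape[0])

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.cfp.shape[1:3]
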
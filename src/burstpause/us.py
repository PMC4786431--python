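"""Unconventional-spike (US) detection and related analyses.

A US is the leading spike pair of a triplet whose first interspike
interval is below a short bound and whose second interval exceeds a long
bound — the signature of a high-frequency burst followed by a pause. The
default bounds are <9 ms and >20 ms; a relaxed variant used for blue-light
responses widens the first bound to <15 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SpikeTrain
from .stats import spearman

__all__ = [
    "USDefinition",
    "USEvent",
    "DEFAULT_US",
    "BLUE_LIGHT_US",
    "detect_us",
    "min_isi_comparison",
    "parameter_sweep",
]


@dataclass(frozen=True)
class USDefinition:
    """ISI bounds of the triplet criterion (both in ms, strict comparisons)."""

    isi1_max: float = 9.0
    isi2_min: float = 20.0

    def __post_init__(self) -> None:
        if self.isi1_max <= 0 or self.isi2_min <= 0:
            raise ValueError("ISI bounds must be positive")


DEFAULT_US = USDefinition(9.0, 20.0)
BLUE_LIGHT_US = USDefinition(15.0, 20.0)


@dataclass(frozen=True)
class USEvent:
    """The designated spike pair (first and second spike of the triplet)."""

    first_spike: float
    second_spike: float
    trial_id: str = ""

    @property
    def isi_ms(self) -> float:
        return (self.second_spike - self.first_spike) * 1000.0


def detect_us(
    train: SpikeTrain,
    definition: USDefinition = DEFAULT_US,
    window: tuple[float, float] | None = None,
    consume: bool = True,
) -> list[USEvent]:
    """Scan consecutive spike triplets for the US signature.

    Triplets ``(s_i, s_{i+1}, s_{i+2})`` are scanned left to right; when
    ``ISI1 < isi1_max`` and ``ISI2 > isi2_min`` (both strict), the pair
    ``(s_i, s_{i+1})`` is emitted. With ``consume=True`` (default) the two
    spikes of an accepted pair are not reused as the start of the next
    triplet; ``consume=False`` scans every triplet (sensitivity mode).

    ``window`` restricts accepted pairs to those whose spikes fall inside
    it; by default the stimulation period of the train's protocol is used,
    or the whole train if no protocol is attached.
    """
    if window is None:
        window = train.protocol.window if train.protocol is not None else None
    t = train.times
    events: list[USEvent] = []
    i = 0
    while i + 2 <= t.size - 1:
        isi1 = (t[i + 1] - t[i]) * 1000.0
        isi2 = (t[i + 2] - t[i + 1]) * 1000.0
        hit = isi1 < definition.isi1_max and isi2 > definition.isi2_min
        if hit and window is not None:
            hit = window[0] <= t[i] and t[i + 1] <= window[1]
        if hit:
            events.append(USEvent(float(t[i]), float(t[i + 1]), train.trial_id))
            i += 2 if consume else 1
        else:
            i += 1
    return events


def min_isi_comparison(
    train: SpikeTrain, us_events: list[USEvent]
) -> tuple[float, float]:
    """Minimum ISI within US pairs versus among non-US consecutive pairs.

    Returns ``(min_us_isi_ms, min_non_us_isi_ms)``. Raises if the trial
    has no US (the within-US minimum is undefined) or no non-US pair.
    """
    if not us_events:
        raise ValueError("within-US minimum ISI undefined: no US in trial")
    us_isis = np.array([e.isi_ms for e in us_events])
    us_pairs = {(round(e.first_spike, 12), round(e.second_spike, 12)) for e in us_events}
    t = train.times
    non_us = [
        (t[j + 1] - t[j]) * 1000.0
        for j in range(t.size - 1)
        if (round(float(t[j]), 12), round(float(t[j + 1]), 12)) not in us_pairs
    ]
    if not non_us:
        raise ValueError("no non-US spike pairs in trial")
    return float(us_isis.min()), float(min(non_us))


def parameter_sweep(
    trials: list[tuple[SpikeTrain, float]],
    grid: list[USDefinition],
    window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Correlate per-trial US counts with Ca2+ amplitudes over a grid of
    US definitions.

    For each definition, the total US number of every trial is computed
    and Spearman-correlated against the trial's ratio-change amplitude.
    Cells where the US count is constant across trials have an undefined
    correlation and are flagged with NaN.
    """
    if len(trials) < 5:
        raise ValueError("need at least 5 trials for the sweep")
    dr = np.array([amp for _, amp in trials], dtype=float)
    rows = []
    for d in grid:
        counts = np.array(
            [len(detect_us(train, d, window=window)) for train, _ in trials],
            dtype=float,
        )
        if np.all(counts == counts[0]):
            rho, p = np.nan, np.nan
        else:
            rho, p = spearman(counts, dr)
        rows.append(
            {
                "isi1_max": d.isi1_max,
                "isi2_min": d.isi2_min,
                "rho": rho,
                "p": p,
                "constant_counts": bool(np.all(counts == counts[0])),
            }
        )
    return pd.DataFrame(rows)
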
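"""Ratiometric FRET Ca2+ imaging pipeline.

The indicator is an intramolecular CFP/YFP FRET sensor (TN-XXL
convention): Ca2+ binding raises the acceptor/donor (YFP/CFP) emission
ratio. The pipeline segments the dendritic arbor from a two-channel
stack, extracts background-subtracted ratio traces from rectangular ROIs,
summarises each trial by the mean ratio change over a fixed window after
stimulus cessation (dR_peak, 400-700 ms by default), and classifies
trials with dR_peak > 10% as Ca2+ transients. Occurrence rates across
trials carry exact Clopper-Pearson intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from skimage import morphology
from skimage.filters import threshold_otsu

from .core import ImageStackPair, RatioTrace
from .stats import clopper_pearson

__all__ = [
    "BinaryMask",
    "BleachFit",
    "build_mask",
    "extract_ratio_trace",
    "dr_peak",
    "classify_transient",
    "occurrence_rate",
    "bleach_baseline",
    "DR_PEAK_WINDOW",
    "TRANSIENT_THRESHOLD_PCT",
]

DR_PEAK_WINDOW = (0.4, 0.7)  # s after stimulus cessation
TRANSIENT_THRESHOLD_PCT = 10.0
BASELINE_WINDOW_S = 1.0  # pre-stimulus baseline for R0


@dataclass(frozen=True)
class BinaryMask:
    """Foreground (arbor) mask plus the parameters that produced it."""

    mask: np.ndarray
    provenance: dict

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))


def build_mask(
    pair: ImageStackPair,
    background_radius: int = 8,
    min_component_px: int = 10,
) -> BinaryMask:
    """Segment the dendritic arbor from a two-channel stack.

    Steps: pixelwise CFP*YFP product per frame (squares the arbor's
    signal-to-background contrast) -> mean projection along time ->
    local-background equalisation by a white top-hat (disk radius
    ``background_radius``) -> Otsu threshold -> suppression of connected
    components smaller than ``min_component_px``.
    """
    if pair.n_frames < 2:
        raise ValueError("need at least two frames to build a mask")
    if not (np.any(pair.cfp > 0) and np.any(pair.yfp > 0)):
        raise ValueError("all-zero stack: no foreground to segment")
    proj = (pair.cfp * pair.yfp).mean(axis=0)
    equalized = morphology.white_tophat(proj, morphology.disk(background_radius))
    if np.allclose(equalized, equalized.flat[0]):
        raise ValueError("degenerate image: no separable foreground after equalisation")
    thr = threshold_otsu(equalized)
    binary = equalized > thr
    binary = morphology.remove_small_objects(binary, max_size=min_component_px - 1)
    if not binary.any():
        raise ValueError("empty mask: no component survived size filtering")
    return BinaryMask(
        binary,
        {
            "background_radius": background_radius,
            "min_component_px": min_component_px,
            "otsu_threshold": float(thr),
        },
    )


def extract_ratio_trace(
    pair: ImageStackPair,
    roi: tuple[int, int, int, int],
    mask: BinaryMask,
    stim_onset: float,
    stim_end: float,
    baseline_s: float = BASELINE_WINDOW_S,
    roi_id: str = "",
    orientation: str = "yfp/cfp",
) -> RatioTrace:
    """Background-subtracted ratio trace of one rectangular ROI.

    ``roi`` is ``(row0, row1, col0, col1)`` with half-open 0-based bounds.
    Within the ROI, signal pixels are those on the binary mask and
    background pixels those off it. Per frame,

        R = (YFP_sig - YFP_bg) / (CFP_sig - CFP_bg)

    (means over the respective pixel sets; inverted for
    ``orientation="cfp/yfp"``), and dR(t) = 100*(R - R0)/R0 where R0 is
    the mean R over the ``baseline_s`` seconds preceding stimulus onset.
    Frames where the denominator is non-positive are flagged and set NaN.
    """
    r0, r1, c0, c1 = roi
    sub = mask.mask[r0:r1, c0:c1]
    if sub.size == 0:
        raise ValueError("empty ROI")
    if not sub.any():
        raise ValueError("ROI does not overlap the mask (no signal pixels)")
    if sub.all():
        raise ValueError("ROI contains no background pixels")
    if orientation not in ("yfp/cfp", "cfp/yfp"):
        raise ValueError("orientation must be 'yfp/cfp' or 'cfp/yfp'")

    cfp = pair.cfp[:, r0:r1, c0:c1]
    yfp = pair.yfp[:, r0:r1, c0:c1]
    sig = sub
    bg = ~sub
    cfp_num = cfp[:, sig].mean(axis=1) - cfp[:, bg].mean(axis=1)
    yfp_num = yfp[:, sig].mean(axis=1) - yfp[:, bg].mean(axis=1)
    if orientation == "yfp/cfp":
        num, den = yfp_num, cfp_num
    else:
        num, den = cfp_num, yfp_num

    flagged = np.flatnonzero(den <= 0)
    ratio = np.full(pair.n_frames, np.nan)
    ok = den > 0
    ratio[ok] = num[ok] / den[ok]

    t = pair.frame_times
    base = ok & (t >= stim_onset - baseline_s) & (t < stim_onset)
    if not base.any():
        raise ValueError("no usable baseline frames before stimulus onset")
    r0_mean = ratio[base].mean()
    if r0_mean == 0:
        raise ValueError("zero baseline ratio")
    dr = 100.0 * (ratio - r0_mean) / r0_mean
    return RatioTrace(t, dr, roi_id=roi_id, stim_end=stim_end, flagged=tuple(flagged))


def dr_peak(trace: RatioTrace, window: tuple[float, float] = DR_PEAK_WINDOW) -> float:
    """Representative trial amplitude: mean dR over a fixed post-stimulus
    window (default 400-700 ms after stimulus cessation), in percent."""
    lo = trace.stim_end + window[0]
    hi = trace.stim_end + window[1]
    if trace.t[-1] < hi - 1e-9:
        raise ValueError("trace does not cover the dR_peak window")
    sel = (trace.t >= lo - 1e-9) & (trace.t <= hi + 1e-9)
    vals = trace.dr[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no usable frames in the dR_peak window")
    return float(vals.mean())


def classify_transient(
    dr_peak_value: float, threshold_pct: float = TRANSIENT_THRESHOLD_PCT
) -> bool:
    """A trial is a Ca2+ transient iff dR_peak is strictly above threshold."""
    return bool(dr_peak_value > threshold_pct)


def occurrence_rate(
    classifications, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """Transient occurrence rate (%) with an exact Clopper-Pearson CI."""
    flags = np.asarray(list(classifications), dtype=bool)
    if flags.size == 0:
        raise ValueError("need at least one classified trial")
    return clopper_pearson(int(flags.sum()), int(flags.size), alpha=alpha)


@dataclass(frozen=True)
class BleachFit:
    """Monoexponential photobleaching baseline ``f(t) = c + A*exp(-k t)``."""

    amplitude: float
    rate: float  # 1/s
    offset: float
    fitted: np.ndarray  # baseline evaluated at every frame time
    residuals: np.ndarray  # trace minus baseline, all frames
    converged: bool


def bleach_baseline(t, f, irradiation_windows=()) -> BleachFit:
    """Fit a photobleaching decay to frames outside irradiation windows.

    Transient heat-dependent dips during irradiation are excluded from the
    fit; the residuals of those frames against the fitted curve quantify
    the attenuation and its recovery. On non-convergence the linear trend
    is returned instead, flagged via ``converged=False``.
    """
    t = np.asarray(t, dtype=float)
    f = np.asarray(f, dtype=float)
    keep = np.ones(t.size, dtype=bool)
    for w0, w1 in irradiation_windows:
        keep &= ~((t >= w0) & (t <= w1))
    if keep.sum() < 3:
        raise ValueError("need at least three frames outside irradiation windows")
    tk, fk = t[keep], f[keep]

    if np.allclose(fk, fk[0]):
        fitted = np.full_like(t, fk[0])
        return BleachFit(0.0, 0.0, float(fk[0]), fitted, f - fitted, True)

    def model(tt, amp, rate, off):
        return off + amp * np.exp(-rate * (tt - t[0]))

    f_inf = fk[-1]
    a0 = max(fk[0] - f_inf, 1e-12)
    k0 = 1.0 / max(tk[-1] - tk[0], 1e-9)
    try:
        popt, _ = curve_fit(
            model, tk, fk, p0=(a0, k0, f_inf),
            bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
        fitted = model(t, *popt)
        return BleachFit(float(popt[0]), float(popt[1]), float(popt[2]),
                         fitted, f - fitted, True)
    except (RuntimeError, ValueError):
        warnings.warn("bleach fit did not converge; returning linear trend", stacklevel=2)
        slope, intercept = np.polyfit(tk, fk, 1)
        fitted = intercept + slope * t
        return BleachFit(0.0, 0.0, float(intercept), fitted, f - fitted, False)
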
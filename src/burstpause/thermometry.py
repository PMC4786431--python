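"""Electrode-resistance thermometry and the IR-laser power model.

The electrical resistance of a saline-filled glass microelectrode falls
with temperature; over the calibration range the relationship follows an
Arrhenius law, linear in reciprocal absolute temperature versus the log
of resistance:

    1/T_K = a + b * ln(R)

A least-squares fit of (R, T) calibration pairs yields the R->T
transformation used to read out the temperature at the laser focus.
Separately, the steady temperature reached under irradiation is linear in
laser output power; the measured slope is 0.6 degC/mW above a 25 degC
ambient, putting a 30 mW stimulus at ~43 degC — just above the larval
nociceptive threshold.

All Arrhenius arithmetic is in kelvin internally; interfaces use Celsius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = [
    "CalibrationModel",
    "PowerModel",
    "fit_arrhenius",
    "resistance_to_temperature",
    "power_to_temperature",
    "KELVIN_OFFSET",
]

KELVIN_OFFSET = 273.15


@dataclass(frozen=True)
class CalibrationModel:
    """Arrhenius coefficients of the R->T transformation."""

    a: float  # intercept, 1/K
    b: float  # slope, 1/K per ln(MOhm)
    fit_domain: tuple[float, float]  # (R_min, R_max), MOhm
    residual_sd: float = 0.0  # sd of 1/T_K residuals
    stderr_a: float = 0.0
    stderr_b: float = 0.0

    def to_dict(self) -> dict:
        return {
            "a": self.a,
            "b": self.b,
            "fit_domain": list(self.fit_domain),
            "residual_sd": self.residual_sd,
            "stderr_a": self.stderr_a,
            "stderr_b": self.stderr_b,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            d["a"], d["b"], tuple(d["fit_domain"]),
            d.get("residual_sd", 0.0), d.get("stderr_a", 0.0), d.get("stderr_b", 0.0),
        )


@dataclass(frozen=True)
class PowerModel:
    """Linear laser-power -> focal-temperature model (driver-set power)."""

    ambient_c: float = 25.0
    slope_c_per_mw: float = 0.6

    def __post_init__(self) -> None:
        if self.slope_c_per_mw <= 0:
            raise ValueError("heating slope must be positive")


def fit_arrhenius(pairs) -> CalibrationModel:
    """Least-squares fit of 1/T_K = a + b*ln(R) to (R_MOhm, T_celsius) pairs."""
    arr = np.asarray(pairs, dtype=float).reshape(-1, 2)
    if arr.shape[0] < 2:
        raise ValueError("need at least two calibration pairs")
    r, t_c = arr[:, 0], arr[:, 1]
    if np.any(r <= 0):
        raise ValueError("resistances must be positive")
    if np.all(r == r[0]):
        raise ValueError("degenerate calibration: constant resistance")
    x = np.log(r)
    y = 1.0 / (t_c + KELVIN_OFFSET)
    res = sstats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    sd = float(np.std(resid, ddof=2)) if arr.shape[0] > 2 else 0.0
    return CalibrationModel(
        a=float(res.intercept),
        b=float(res.slope),
        fit_domain=(float(r.min()), float(r.max())),
        residual_sd=sd,
        stderr_a=float(getattr(res, "intercept_stderr", 0.0) or 0.0),
        stderr_b=float(res.stderr or 0.0),
    )


def resistance_to_temperature(r_mohm, model: CalibrationModel):
    """Apply the R->T transformation; returns Celsius.

    Extrapolation outside the fitted resistance range is allowed but
    warned about; an inverse absolute temperature that is not positive is
    an error (the model cannot represent it).
    """
    r = np.asarray(r_mohm, dtype=float)
    if np.any(r <= 0):
        raise ValueError("resistance must be positive")
    if np.any(r < model.fit_domain[0]) or np.any(r > model.fit_domain[1]):
        warnings.warn("resistance outside calibration domain; extrapolating", stacklevel=2)
    inv_t = model.a + model.b * np.log(r)
    if np.any(inv_t <= 0):
        raise ValueError("model yields non-positive inverse temperature")
    t_c = 1.0 / inv_t - KELVIN_OFFSET
    return float(t_c) if np.isscalar(r_mohm) else t_c


def power_to_temperature(power_mw, model: PowerModel = PowerModel()):
    """Steady focal temperature (Celsius) at a driver-set laser power (mW)."""
    p = np.asarray(power_mw, dtype=float)
    if np.any(p < 0):
        raise ValueError("laser power must be nonnegative")
    t = model.ambient_c + model.slope_c_per_mw * p
    return float(t) if np.isscalar(power_mw) else t
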
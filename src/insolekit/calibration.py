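"""Sensor-physics arithmetic for the insole's analog front end.

Every channel of the insole — force-sensitive resistor (FSR) or NTC
thermistor — is read through the same pull-up voltage divider:

    Vout = Vcc * Rext / (Rext + Rsensor)

so converting an ADC count to a physical quantity is always the chain
count -> voltage -> resistance -> (force | temperature).  This module
implements each link as a pure, vectorised function plus the inverse
links the simulator needs, the exponential thermistor calibration fit,
and the pressure/force/mass conversions used to size the sensing range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DividerConfig",
    "ThermistorModel",
    "FSRForceModel",
    "SensorGeometry",
    "OpenCircuitError",
    "CalibrationFit",
    "adc_to_voltage",
    "voltage_to_adc",
    "resistance_from_voltage",
    "voltage_from_resistance",
    "thermistor_resistance_from_adc",
    "temperature_from_resistance",
    "temperature_from_adc",
    "fit_exponential_calibration",
    "active_area",
    "force_from_pressure",
    "mass_from_force",
    "force_from_resistance",
    "resistance_from_force",
    "TEMP_WORKING_RANGE_C",
]

#: NTC working range (deg C) of the selected thermistor; readings outside
#: this band are physically possible but outside the calibrated region.
TEMP_WORKING_RANGE_C = (20.0, 50.0)

STANDARD_GRAVITY = 9.81  # m/s^2


class OpenCircuitError(ValueError):
    """Raised when a reading implies an unloaded/open sensor (R -> infinity)."""


@dataclass(frozen=True)
class DividerConfig:
    """One voltage-divider channel: supply, pull-up and ADC resolution.

    Defaults match a 5 V supply, a 10 kOhm external pull-up and the
    ESP32's 12-bit ADC (counts 0..4095).
    """

    vcc: float = 5.0
    r_ext: float = 10_000.0
    adc_bits: int = 12

    def __post_init__(self) -> None:
        if self.vcc <= 0:
            raise ValueError(f"vcc must be > 0, got {self.vcc}")
        if self.r_ext <= 0:
            raise ValueError(f"r_ext must be > 0, got {self.r_ext}")
        if self.adc_bits < 1:
            raise ValueError(f"adc_bits must be >= 1, got {self.adc_bits}")

    @property
    def adc_max(self) -> int:
        return 2**self.adc_bits - 1


@dataclass(frozen=True)
class ThermistorModel:
    """Exponential NTC calibration  R(T) = a * exp(b * T).

    ``a`` is the extrapolated resistance at 0 deg C (Ohm) and ``b`` the
    exponential rate (1/degC, negative for an NTC).  Defaults are the
    fitted curve of the reference thermistor: a = 24,710 Ohm,
    b = -0.036 /degC.
    """

    a: float = 24_710.0
    b: float = -0.036

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"coefficient a must be > 0, got {self.a}")
        if self.b >= 0:
            raise ValueError(f"NTC rate b must be < 0, got {self.b}")

    def resistance_at(self, temperature_c):
        """Forward model: resistance (Ohm) at a temperature (deg C)."""
        return self.a * np.exp(self.b * np.asarray(temperature_c, dtype=float))


# Default FSR-402-like anchor table.  The sensor datasheet fixes one point
# exactly (10 kOhm at 100 g, i.e. 0.981 N under g = 9.81); the remaining
# anchors follow the inverse power law R * F = 9810 Ohm*N through that
# point, a reconstruction of the typical FSR response (resistance falls
# roughly as 1/force).  Supply your own table for a characterised sensor.
_DEFAULT_FSR_ANCHORS: tuple[tuple[float, float], ...] = (
    (100_000.0, 0.0981),
    (31_600.0, 0.3104),
    (10_000.0, 0.981),
    (3_160.0, 3.1044),
    (1_000.0, 9.81),
    (316.0, 31.044),
    (100.0, 98.1),
)


@dataclass(frozen=True)
class FSRForceModel:
    """Monotone FSR resistance -> force curve from an anchor table.

    Anchors are (resistance Ohm, force N) pairs, interpolated
    log-log-linearly.  Resistance must be strictly decreasing as force
    increases.  Above the largest-resistance anchor the sensor is treated
    as unloaded (0 N); below the smallest, the last log-log segment is
    extrapolated.
    """

    anchors: tuple[tuple[float, float], ...] = _DEFAULT_FSR_ANCHORS

    # sorted views cached at construction (ascending resistance)
    _log_r: np.ndarray = field(init=False, repr=False, compare=False)
    _log_f: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ValueError("FSRForceModel needs at least 2 anchors")
        arr = np.asarray(self.anchors, dtype=float)
        if np.any(arr <= 0):
            raise ValueError("anchor resistances and forces must be > 0")
        order = np.argsort(arr[:, 0])
        r, f = arr[order, 0], arr[order, 1]
        if np.any(np.diff(r) <= 0) or np.any(np.diff(f) >= 0):
            raise ValueError(
                "anchors must have strictly decreasing resistance as force increases"
            )
        object.__setattr__(self, "_log_r", np.log(r))
        object.__setattr__(self, "_log_f", np.log(f))

    @property
    def max_resistance(self) -> float:
        return float(np.exp(self._log_r[-1]))

    @property
    def max_force(self) -> float:
        return float(np.exp(self._log_f[0]))


# ---------------------------------------------------------------------------
# ADC <-> voltage


def adc_to_voltage(adc_count, cfg: DividerConfig = DividerConfig()):
    """Map ADC counts linearly onto [0, Vcc]; full scale reads Vcc exactly.

    Counts may be real-valued (the quantisation step lives in the
    simulator, not here).
    """
    a = np.asarray(adc_count, dtype=float)
    if np.any(a < 0) or np.any(a > cfg.adc_max):
        bad = a[(a < 0) | (a > cfg.adc_max)]
        raise ValueError(
            f"ADC count(s) {np.atleast_1d(bad)[:5]} outside [0, {cfg.adc_max}]"
        )
    out = cfg.vcc * a / cfg.adc_max
    return out if out.ndim else float(out)


def voltage_to_adc(vout, cfg: DividerConfig = DividerConfig()):
    """Inverse of :func:`adc_to_voltage` (real-valued, not quantised)."""
    v = np.asarray(vout, dtype=float)
    if np.any(v < 0) or np.any(v > cfg.vcc):
        raise ValueError(f"voltage outside [0, {cfg.vcc}] V")
    out = v / cfg.vcc * cfg.adc_max
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# voltage <-> resistance (pull-up divider)


def resistance_from_voltage(vout, cfg: DividerConfig = DividerConfig()):
    """Invert the pull-up divider:  R = Rext * (Vcc - Vout) / Vout.

    ``vout == vcc`` gives 0 Ohm; ``vout <= 0`` means no current flows
    through the pull-up, i.e. an open circuit, and raises
    :class:`OpenCircuitError`.
    """
    v = np.asarray(vout, dtype=float)
    if np.any(v <= 0):
        raise OpenCircuitError("Vout <= 0 V: open circuit / infinite resistance")
    if np.any(v > cfg.vcc):
        raise ValueError(f"Vout exceeds supply {cfg.vcc} V: invalid reading")
    out = cfg.r_ext * (cfg.vcc - v) / v
    return out if out.ndim else float(out)


def voltage_from_resistance(r, cfg: DividerConfig = DividerConfig()):
    """Forward divider: Vout = Vcc * Rext / (Rext + R).  R = inf -> 0 V."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ValueError("resistance must be >= 0")
    with np.errstate(invalid="ignore"):
        out = np.where(
            np.isinf(r_arr), 0.0, cfg.vcc * cfg.r_ext / (cfg.r_ext + r_arr)
        )
    return out if out.ndim else float(out)


def thermistor_resistance_from_adc(adc_count, cfg: DividerConfig = DividerConfig()):
    """Thermistor resistance from a raw count:  R = Rext * (adc_max - A) / A.

    With the default 5 V / 10 kOhm / 12-bit configuration this is the
    closed form R = (40,950,000 - 10,000 A) / A, and it is algebraically
    identical to composing :func:`adc_to_voltage` with
    :func:`resistance_from_voltage` for any configuration.
    """
    a = np.asarray(adc_count, dtype=float)
    if np.any(a <= 0):
        raise OpenCircuitError("ADC count 0: open circuit / infinite resistance")
    if np.any(a > cfg.adc_max):
        raise ValueError(f"ADC count exceeds full scale {cfg.adc_max}")
    out = cfg.r_ext * (cfg.adc_max - a) / a
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# resistance <-> temperature


def temperature_from_resistance(r, model: ThermistorModel = ThermistorModel()):
    """Invert the exponential calibration:  T = (ln R - ln a) / b."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("resistance must be > 0 for the log inversion")
    out = (np.log(r_arr) - math.log(model.a)) / model.b
    lo, hi = TEMP_WORKING_RANGE_C
    if np.any(out < lo) or np.any(out > hi):
        warnings.warn(
            f"temperature outside the calibrated working range {lo}-{hi} degC",
            stacklevel=2,
        )
    return out if out.ndim else float(out)


def temperature_from_adc(
    adc_count,
    cfg: DividerConfig = DividerConfig(),
    model: ThermistorModel = ThermistorModel(),
):
    """Temperature directly from a raw count (divider + calibration chain).

    Equals ``temperature_from_resistance(thermistor_resistance_from_adc(A))``
    by construction; counts at 0 or full scale have no finite temperature
    (ln of infinity or zero) and are rejected.
    """
    a = np.asarray(adc_count, dtype=float)
    if np.any(a >= cfg.adc_max):
        raise ValueError("full-scale count: RTemp = 0, temperature undefined")
    return temperature_from_resistance(
        thermistor_resistance_from_adc(a, cfg), model
    )


@dataclass(frozen=True)
class CalibrationFit:
    """Result of the exponential thermistor fit."""

    model: ThermistorModel
    r_squared: float  # R^2 of the linear fit on ln(resistance)


def fit_exponential_calibration(pairs) -> CalibrationFit:
    """Fit R(T) = a * exp(b T) by least squares on ln(R) vs T.

    Parameters
    ----------
    pairs
        Iterable of (temperature degC, resistance Ohm).  At least two
        distinct temperatures; resistances must be positive.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 2:
        raise ValueError("need >= 2 (temperature, resistance) pairs")
    t, r = arr[:, 0], arr[:, 1]
    if np.any(r <= 0):
        raise ValueError("all resistances must be > 0")
    if np.unique(t).size < 2:
        raise ValueError("need at least two distinct temperatures")
    res = stats.linregress(t, np.log(r))
    model = ThermistorModel(a=float(np.exp(res.intercept)), b=float(res.slope))
    # rvalue is 0/0 -> nan only for degenerate inputs already rejected
    return CalibrationFit(model=model, r_squared=float(res.rvalue**2))


# ---------------------------------------------------------------------------
# force / pressure / mass


def active_area(radius_mm: float) -> float:
    """Circular active sensing area (mm^2); the FSR-402 radius is 6.35 mm."""
    if radius_mm < 0:
        raise ValueError(f"radius must be >= 0, got {radius_mm}")
    return math.pi * radius_mm**2


@dataclass(frozen=True)
class SensorGeometry:
    """Active area of one circular pressure sensor."""

    radius_mm: float = 6.35

    def __post_init__(self) -> None:
        if self.radius_mm < 0:
            raise ValueError("radius must be >= 0")

    @property
    def area_mm2(self) -> float:
        return active_area(self.radius_mm)


def force_from_pressure(pressure_pa, area_mm2):
    """Force (N) = pressure (Pa) * area (mm^2) * 1e-6 (mm^2 -> m^2)."""
    p = np.asarray(pressure_pa, dtype=float)
    a = np.asarray(area_mm2, dtype=float)
    if np.any(p < 0) or np.any(a < 0):
        raise ValueError("pressure and area must be >= 0")
    out = p * a * 1e-6
    return out if out.ndim else float(out)


def mass_from_force(force_n, g: float = STANDARD_GRAVITY):
    """Equivalent mass (kg) of a normal force under gravity g (m/s^2)."""
    if g <= 0:
        raise ValueError(f"g must be > 0, got {g}")
    f = np.asarray(force_n, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be >= 0")
    out = f / g
    return out if out.ndim else float(out)


def force_from_resistance(r, model: FSRForceModel = FSRForceModel()):
    """Force (N) on an FSR from its resistance via the anchor table.

    Log-log linear interpolation between anchors (exact at anchors,
    monotone non-increasing in resistance); above the largest anchor
    resistance the sensor is unloaded and the force is 0 N.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("resistance must be > 0")
    log_r = np.log(r_arr)
    # np.interp needs ascending x; force decreases with resistance
    log_f = np.interp(log_r, model._log_r, model._log_f)
    # extrapolate below the smallest anchor along the first segment
    lo = log_r < model._log_r[0]
    if np.any(lo):
        slope = (model._log_f[1] - model._log_f[0]) / (
            model._log_r[1] - model._log_r[0]
        )
        log_f = np.where(
            lo, model._log_f[0] + slope * (log_r - model._log_r[0]), log_f
        )
    out = np.where(log_r > model._log_r[-1], 0.0, np.exp(log_f))
    return out if out.ndim else float(out)


def resistance_from_force(force_n, model: FSRForceModel = FSRForceModel()):
    """Inverse of :func:`force_from_resistance`; zero force -> open (inf)."""
    f = np.asarray(force_n, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be >= 0")
    with np.errstate(divide="ignore"):
        log_f = np.log(f)
    # ascending force = reversed anchor order
    lf, lr = model._log_f[::-1], model._log_r[::-1]
    log_r = np.interp(log_f, lf, lr)
    # extrapolate both ends along the terminal log-log segments, so a
    # force below the lightest anchor maps past the largest resistance
    # (read back as unloaded) instead of clamping to it
    hi = log_f > lf[-1]
    if np.any(hi):
        slope = (lr[-1] - lr[-2]) / (lf[-1] - lf[-2])
        log_r = np.where(hi, lr[-1] + slope * (log_f - lf[-1]), log_r)
    lo = log_f < lf[0]
    if np.any(lo):
        slope = (lr[1] - lr[0]) / (lf[1] - lf[0])
        log_r = np.where(lo, lr[0] + slope * (log_f - lf[0]), log_r)
    out = np.where(f == 0, np.inf, np.exp(log_r))
    return out if out.ndim else float(out)
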
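"""Single-point Nernstian calibration of an ISFET pH sensor.

An ISFET pH electrode (e.g. the Durafet inside a SeaFET logger) reports a
voltage that is linear in pH with the Nernst slope R·T·ln(10)/F, offset by a
sensor-specific reference potential E*.  One discrete bottle sample of known
pH (converted from its bench value at 25 °C to in-situ temperature via the
carbonate system) pins down E*; the whole deployment's voltage record is then
converted to total-scale pH through the same equation.

With one bottle per deployment, drift is unidentifiable and no drift model is
attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, InvalidConfigError
from .series import EnvironmentalSeries

#: CODATA gas constant, J mol^-1 K^-1.
R_GAS = 8.314462618
#: Faraday constant, C mol^-1.
FARADAY = 96485.332
LN10 = np.log(10.0)


@dataclass
class BottleSample:
    """Discrete calibration sample: bench chemistry plus in-situ temperature."""

    timestamp: np.datetime64
    ph25_total: float  # total-scale pH measured at 25 degC
    alkalinity: float  # umol / kg-SW
    salinity: float
    temperature_insitu: float  # degC at collection

    def __post_init__(self) -> None:
        if not 7.0 < self.ph25_total < 9.0:
            raise InvalidConfigError(f"bottle pH25 {self.ph25_total} outside (7, 9)")
        if not 1500.0 < self.alkalinity < 3000.0:
            raise InvalidConfigError(f"bottle alkalinity {self.alkalinity} outside (1500, 3000)")
        if not 20.0 < self.salinity < 40.0:
            raise InvalidConfigError(f"bottle salinity {self.salinity} outside (20, 40)")
        self.timestamp = np.datetime64(self.timestamp, "ns")


@dataclass
class CalibrationFit:
    """Fitted sensor reference potential and its provenance."""

    e_star: float  # volts
    calibration_time: np.datetime64 | None
    slope_at_calibration: float  # volts per pH unit

    def __post_init__(self) -> None:
        if not np.isfinite(self.e_star):
            raise InvalidConfigError("e_star must be finite")
        if self.slope_at_calibration <= 0:
            raise InvalidConfigError("slope_at_calibration must be positive")

    def to_json(self, path, *, bottle: BottleSample | None = None) -> None:
        rec = {
            "e_star_V": self.e_star,
            "calibration_time": None
            if self.calibration_time is None
            else str(self.calibration_time),
            "slope_at_calibration_V_per_pH": self.slope_at_calibration,
        }
        if bottle is not None:
            rec["bottle"] = {
                "timestamp": str(bottle.timestamp),
                "ph25_total": bottle.ph25_total,
                "alkalinity_umol_kg": bottle.alkalinity,
                "salinity": bottle.salinity,
                "temperature_insitu_C": bottle.temperature_insitu,
            }
        with open(path, "w") as fh:
            json.dump(rec, fh, indent=1)


def nernst_slope(temperature_K):
    """Nernst slope R·T·ln(10)/F in volts per pH unit at absolute temperature."""
    temperature_K = np.asarray(temperature_K, dtype=float)
    if np.any(temperature_K <= 0):
        raise InvalidConfigError("absolute temperature must be positive")
    out = R_GAS * temperature_K * LN10 / FARADAY
    return float(out) if out.ndim == 0 else out


def estimate_e_star(
    voltage_at_cal: float,
    bottle_ph_insitu: float,
    temperature_insitu_K: float,
    *,
    calibration_time=None,
) -> CalibrationFit:
    """Solve V = E* + slope(T)·pH for E* at the calibration instant.

    ``bottle_ph_insitu`` must already be at in-situ temperature (see
    :func:`reefwave.carbonate.ph25_to_insitu`).
    """
    slope = nernst_slope(temperature_insitu_K)
    e_star = voltage_at_cal - slope * bottle_ph_insitu
    t = None if calibration_time is None else np.datetime64(calibration_time, "ns")
    return CalibrationFit(e_star=float(e_star), calibration_time=t, slope_at_calibration=float(slope))


def calibrate_from_bottles(
    voltage: EnvironmentalSeries,
    temperature: EnvironmentalSeries,
    bottles: "BottleSample | list[BottleSample]",
) -> CalibrationFit:
    """Calibrate against discrete bottle sample(s).

    Exactly one bottle is supported (one bottle per deployment); the interface
    accepts a list so a multi-point regression can slot in later, but errors
    for now if more than one is supplied.

    The bottle's bench pH (25 °C) is converted to in-situ temperature through
    the carbonate system, and the sensor voltage and thermistor temperature are
    linearly interpolated to the bottle timestamp.
    """
    from . import carbonate  # deferred: carbonate is independent of calibration

    if isinstance(bottles, BottleSample):
        bottles = [bottles]
    if len(bottles) != 1:
        raise NotImplementedError("multi-point calibration is not implemented; supply one bottle")
    bottle = bottles[0]
    if not voltage.same_grid(temperature):
        raise AlignmentError("voltage and temperature series must share one time grid")

    ph_insitu = carbonate.ph25_to_insitu(
        bottle.ph25_total, bottle.alkalinity, bottle.temperature_insitu, bottle.salinity
    )
    t_cal = (bottle.timestamp - voltage.timestamps[0]) / np.timedelta64(1, "s")
    tt = voltage.t_seconds[voltage.valid & temperature.valid]
    if not tt.size or t_cal < tt[0] or t_cal > tt[-1]:
        raise InvalidConfigError("bottle timestamp lies outside the valid sensor record")
    v_cal = float(np.interp(t_cal, tt, voltage.values[voltage.valid & temperature.valid]))
    T_cal = bottle.temperature_insitu + 273.15
    return estimate_e_star(v_cal, ph_insitu, T_cal, calibration_time=bottle.timestamp)


def voltage_to_ph(
    voltage: EnvironmentalSeries,
    temperature: EnvironmentalSeries,
    fit: CalibrationFit,
) -> EnvironmentalSeries:
    """Convert a raw voltage record to total-scale pH: pH_t = (V_t − E*)/slope(T_t)."""
    if not voltage.same_grid(temperature):
        raise AlignmentError("voltage and temperature series must share one time grid")
    slope = nernst_slope(temperature.values + 273.15)
    ph = (voltage.values - fit.e_star) / slope
    return EnvironmentalSeries(
        site=voltage.site,
        variable="pH_total",
        timestamps=voltage.timestamps.copy(),
        values=ph,
        valid=voltage.valid & temperature.valid,
    )
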
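"""Sensor geometry and RTD calibration physics.

The microchip carries a platinum microheater, three resistance temperature
detectors (RTDs) and concentric interdigitated electrodes (IDEs).  The two
quantities this module owns are

* the dimensionless geometric factor ``2*pi / ln(D2/D1)`` that converts a
  measured surface resistance between the concentric IDE rings into a sheet
  resistivity (ohm per square), and
* the linear RTD law ``R(T) = R0 * (1 + alpha * (T - T0))`` with its
  forward, inverse and least-squares calibration forms.

All lengths are SI metres internally; the default electrode diameters are
D1 = 130 um (outer diameter of the inner electrode) and D2 = 140 um (inner
diameter of the outer electrode), which give a geometric factor of 84.8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateFitError, InvalidGeometryError, InvalidMeasurementError

__all__ = [
    "ChipGeometry",
    "RTDCalibration",
    "geometric_factor",
    "rtd_resistance_to_temperature",
    "temperature_to_resistance",
    "fit_rtd_calibration",
    "heater_power",
]


@dataclass(frozen=True)
class ChipGeometry:
    """Fixed geometry of one sensing microchip (SI units).

    ``electrode_area`` is the cross-sectional area of the outer electrode
    used by the bulk-resistivity formula ``rho_B = R_B * A / l``.  Its
    absolute value is conventional (the chip drawing does not pin it down);
    the default is the disc area ``pi * (D2 / 2)**2``.  Forward simulation
    and inversion share the same instance, so recovered resistivities are
    independent of the convention.
    """

    d1_inner_electrode_outer_diam: float = 130e-6
    d2_outer_electrode_inner_diam: float = 140e-6
    electrode_area: float | None = None
    active_region: tuple[float, float] = (1.0e-3, 0.5e-3)
    chip_extent: tuple[float, float] = (12.0e-3, 7.0e-3)
    trench_depth: float = 350e-6

    def __post_init__(self) -> None:
        d1 = self.d1_inner_electrode_outer_diam
        d2 = self.d2_outer_electrode_inner_diam
        if not (d2 > d1 > 0.0):
            raise InvalidGeometryError(
                f"require D2 > D1 > 0, got D1={d1!r}, D2={d2!r}"
            )
        if self.electrode_area is None:
            object.__setattr__(self, "electrode_area", math.pi * (d2 / 2.0) ** 2)
        if self.electrode_area <= 0.0:
            raise InvalidGeometryError(f"electrode_area must be > 0, got {self.electrode_area!r}")


@dataclass(frozen=True)
class RTDCalibration:
    """Linear RTD law ``R(T) = r0 * (1 + alpha * (T - t0))``.

    ``alpha`` is the temperature coefficient of resistance (per deg C) of the
    thin-film platinum element; the fabricated devices measure at 2.2e-3.
    A single first-order coefficient is used throughout — the devices are
    characterised by one TCR, so no quadratic (Callendar-Van Dusen) term.
    """

    r0: float = 100.0
    t0: float = 25.0
    alpha: float = 2.2e-3

    def __post_init__(self) -> None:
        if self.r0 <= 0.0:
            raise InvalidMeasurementError(f"r0 must be > 0, got {self.r0!r}")
        if self.alpha <= 0.0:
            raise InvalidMeasurementError(f"alpha must be > 0, got {self.alpha!r}")


def geometric_factor(geometry: ChipGeometry) -> float:
    """Dimensionless factor ``2*pi / ln(D2/D1)`` for concentric IDEs.

    Multiplies the measured surface resistance to give sheet resistivity.
    Scale-invariant: depends only on the diameter ratio.
    """
    d1 = geometry.d1_inner_electrode_outer_diam
    d2 = geometry.d2_outer_electrode_inner_diam
    if not (d2 > d1 > 0.0):
        raise InvalidGeometryError("geometric factor needs D2 > D1 > 0")
    return 2.0 * math.pi / math.log(d2 / d1)


def temperature_to_resistance(t: float, calib: RTDCalibration) -> float:
    """Forward RTD law: resistance (ohm) at temperature ``t`` (deg C)."""
    return calib.r0 * (1.0 + calib.alpha * (t - calib.t0))


def rtd_resistance_to_temperature(r: float, calib: RTDCalibration) -> float:
    """Invert the linear RTD law: temperature (deg C) for resistance ``r``."""
    if r <= 0.0:
        raise InvalidMeasurementError(f"RTD resistance must be > 0, got {r!r}")
    return calib.t0 + (r / calib.r0 - 1.0) / calib.alpha


def fit_rtd_calibration(
    pairs: Sequence[tuple[float, float]], t0: float = 25.0
) -> RTDCalibration:
    """Least-squares RTD calibration from (temperature, resistance) pairs.

    Fits the line ``R = a + b * (T - t0)`` by ordinary least squares and
    returns ``RTDCalibration(r0=a, t0=t0, alpha=b / a)``.  On noiseless
    linear input the generating coefficients are recovered to machine
    precision.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise DegenerateFitError("need at least two (temperature, resistance) pairs")
    temps, res = arr[:, 0], arr[:, 1]
    if np.ptp(temps) == 0.0:
        raise DegenerateFitError("all calibration temperatures are identical")
    slope, intercept = np.polyfit(temps - t0, res, 1)
    if intercept <= 0.0:
        raise DegenerateFitError("fitted r0 is nonpositive; calibration data invalid")
    return RTDCalibration(r0=float(intercept), t0=float(t0), alpha=float(slope / intercept))


def heater_power(v: float, i: float) -> float:
    """Joule power Q = V * I (watt) dissipated in the microheater."""
    if v < 0.0 or i < 0.0:
        raise InvalidMeasurementError(f"voltage and current must be >= 0, got {v!r}, {i!r}")
    return v * i
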
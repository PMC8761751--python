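"""Inversion of raw measurement records into electrothermal parameters.

Three estimators, one per parameter:

* bulk resistivity      ``rho_B = R_B * A / l``        (ohm m, reported ohm cm)
* surface resistivity   ``rho_S = g * R_s``            (ohm per square),
  with ``g = 2 pi / ln(D2/D1)`` the concentric-IDE geometric factor
* thermal conductivity  ``k = Q * l / (A * dT)``       (W m^-1 K^-1),

where ``Q`` is the heater Joule power, ``l`` the sample thickness, ``A``
the relevant cross-section and ``dT`` the steady-state drop between the
heater source temperature and the triangulated sink temperature read by
the three RTDs on the opposite chip.  The thermal form is the steady-state
ex vivo reduction of the tissue bioheat balance: with no perfusion or
metabolic generation the transient equation collapses to Poisson
conduction, and under uniform heating to a 1-D series resistance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chip_model import ChipGeometry, RTDCalibration, geometric_factor, heater_power, rtd_resistance_to_temperature
from .errors import InputError, InvalidMeasurementError, NoGradientError, SensorFailureError
from .synthetic_study import MeasurementRecord, SampleGeometry

__all__ = [
    "ProfileEntry",
    "ElectrothermalProfile",
    "bulk_resistivity",
    "surface_resistivity",
    "sink_temperature",
    "thermal_conductivity",
    "build_profile",
    "profiles_to_frame",
]

logger = logging.getLogger(__name__)

OHM_M_TO_OHM_CM = 100.0


def bulk_resistivity(r_b: float, electrode_area: float, thickness: float) -> float:
    """Bulk resistivity ``rho_B = R_B * A / l`` in ohm m (SI).

    ``r_b`` is the through-tissue resistance (ohm), ``electrode_area`` the
    outer-electrode cross-section (m^2), ``thickness`` the sample thickness
    (m).  Multiply by 100 for the ohm cm reporting unit.
    """
    if r_b <= 0.0 or electrode_area <= 0.0 or thickness <= 0.0:
        raise InvalidMeasurementError(
            f"all inputs must be > 0, got r_b={r_b!r}, A={electrode_area!r}, l={thickness!r}"
        )
    return r_b * electrode_area / thickness


def surface_resistivity(r_s: float, geometry: ChipGeometry) -> float:
    """Sheet resistivity ``rho_S = g * R_s`` in ohm per square."""
    if r_s <= 0.0:
        raise InvalidMeasurementError(f"surface resistance must be > 0, got {r_s!r}")
    return geometric_factor(geometry) * r_s


def sink_temperature(rtd_resistances: Sequence[float], calib: RTDCalibration) -> float:
    """Triangulated sink temperature: mean over the valid RTD readings.

    The three RTDs sit symmetrically around the sink-side heater structure;
    with no published coordinates the triangulation is the unweighted mean.
    Readings that are nonpositive or non-finite are dropped with a warning;
    at least one valid reading is required.
    """
    vals = [r for r in rtd_resistances if r is not None and np.isfinite(r) and r > 0.0]
    if not vals:
        raise SensorFailureError("no valid RTD reading among the sink sensors")
    if len(vals) < len(rtd_resistances):
        logger.warning(
            "only %d of %d sink RTDs valid; triangulating from the rest",
            len(vals), len(rtd_resistances),
        )
    return float(np.mean([rtd_resistance_to_temperature(r, calib) for r in vals]))


def thermal_conductivity(
    q: float, thickness: float, contact_area: float, t_source: float, t_sink: float
) -> float:
    """Steady-state conductivity ``k = Q * l / (A * dT)`` in W m^-1 K^-1.

    ``dT = t_source - t_sink`` in deg C (identical to kelvin for a
    difference) must be positive: the estimator is undefined with the
    heater off or before a steady gradient is established.
    """
    if q <= 0.0 or thickness <= 0.0 or contact_area <= 0.0:
        raise InvalidMeasurementError("q, thickness and contact_area must be > 0")
    delta_t = t_source - t_sink
    if delta_t <= 0.0:
        raise NoGradientError(
            f"no positive source-sink gradient (dT={delta_t!r} K); steady state not reached"
        )
    return q * thickness / (contact_area * delta_t)


@dataclass(frozen=True)
class ProfileEntry:
    """Inferred parameters of one sample at one setpoint (reporting units)."""

    temperature_c: float
    rho_b_ohm_cm: float
    rho_s_ohm_sq: float
    k_w_m_k: float
    delta_t_k: float
    q_w: float
    missing: bool = False


@dataclass(frozen=True)
class ElectrothermalProfile:
    """Per-setpoint inferred rho_B, rho_S, k of one sample."""

    sample_id: str
    patient_id: str
    group: str
    preparation: str
    entries: tuple[ProfileEntry, ...]

    def at(self, temperature_c: float) -> ProfileEntry:
        for e in self.entries:
            if math.isclose(e.temperature_c, temperature_c, abs_tol=1e-9):
                return e
        raise KeyError(f"no entry at {temperature_c} deg C for {self.sample_id}")

    @property
    def temperatures(self) -> tuple[float, ...]:
        return tuple(e.temperature_c for e in self.entries)


def _invert_record(
    rec: MeasurementRecord,
    chip: ChipGeometry,
    calib: RTDCalibration,
    geometry: SampleGeometry,
) -> ProfileEntry:
    q = heater_power(rec.heater_v, rec.heater_i)
    t_sink = sink_temperature(rec.rtd_resistances, calib)
    k = thermal_conductivity(
        q, geometry.thickness, geometry.contact_area, rec.t_source_c, t_sink
    )
    rho_b = bulk_resistivity(rec.r_bulk_ohm, chip.electrode_area, geometry.thickness)
    # Two chips read the same sheet; average their surface resistances.
    r_s = 0.5 * (rec.r_surf1_ohm + rec.r_surf2_ohm)
    rho_s = surface_resistivity(r_s, chip)
    return ProfileEntry(
        temperature_c=rec.setpoint_c,
        rho_b_ohm_cm=rho_b * OHM_M_TO_OHM_CM,
        rho_s_ohm_sq=rho_s,
        k_w_m_k=k,
        delta_t_k=rec.t_source_c - t_sink,
        q_w=q,
    )


def build_profile(
    records: Iterable[MeasurementRecord],
    chip: ChipGeometry,
    calib: RTDCalibration,
    geometry: SampleGeometry,
) -> ElectrothermalProfile:
    """Invert all of one sample's records into an ElectrothermalProfile.

    Records must share a single sample id; entries come out sorted by
    setpoint.  A record whose observables cannot be inverted yields an
    entry flagged ``missing`` (NaN parameters) while the others are still
    computed.
    """
    recs = sorted(records, key=lambda r: r.setpoint_c)
    if not recs:
        raise InputError("need at least one measurement record")
    ids = {r.sample_id for r in recs}
    if len(ids) != 1:
        raise InputError(f"records mix sample ids: {sorted(ids)}")
    entries = []
    for rec in recs:
        try:
            entries.append(_invert_record(rec, chip, calib, geometry))
        except (InvalidMeasurementError, SensorFailureError, NoGradientError) as exc:
            logger.warning(
                "sample %s setpoint %s: %s; entry flagged missing",
                rec.sample_id, rec.setpoint_c, exc,
            )
            entries.append(
                ProfileEntry(
                    temperature_c=rec.setpoint_c,
                    rho_b_ohm_cm=math.nan, rho_s_ohm_sq=math.nan, k_w_m_k=math.nan,
                    delta_t_k=math.nan, q_w=math.nan, missing=True,
                )
            )
    first = recs[0]
    return ElectrothermalProfile(
        sample_id=first.sample_id,
        patient_id=first.patient_id,
        group=first.group,
        preparation=first.preparation,
        entries=tuple(entries),
    )


def profiles_to_frame(profiles: Iterable[ElectrothermalProfile]) -> pd.DataFrame:
    """Tidy DataFrame of profiles: one row per sample per setpoint."""
    rows = []
    for prof in profiles:
        for e in prof.entries:
            rows.append(
                {
                    "sample_id": prof.sample_id,
                    "patient_id": prof.patient_id,
                    "group": prof.group,
                    "preparation": prof.preparation,
                    "temperature_c": e.temperature_c,
                    "rho_b_ohm_cm": e.rho_b_ohm_cm,
                    "rho_s_ohm_sq": e.rho_s_ohm_sq,
                    "k_w_m_k": e.k_w_m_k,
                    "delta_t_k": e.delta_t_k,
                    "q_w": e.q_w,
                    "missing": e.missing,
                }
            )
    return pd.DataFrame(rows)
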
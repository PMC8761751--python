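"""Synthetic tissue cohorts and raw measurement records.

The original cohort's per-sample data were never published; this module
generates cohorts with the same design — N patients split across
deparaffinized and formalin-fixed preparations, paired tumor / adjacent
normal blocks, three technical repeats each, a 25 -> 37 deg C ramp in 3 deg
steps — and with group-level statistics matched to the published summary
tables (:mod:`etpheno.reference`).

Sampling model
--------------
For each electrothermal parameter (rho_B, rho_S, k) a sample draws its
25 deg C and 37 deg C values from a correlated bivariate lognormal whose
marginal means and standard deviations are moment-matched to the published
group mean and spread (spread read as SEM with n = 12, so per-sample
SD = spread * sqrt(12)).  The within-sample correlation between the two
endpoints is calibrated so that the implied paired-t statistic of the
37-vs-25 contrast matches the published p-value for that group; this is
what reproduces the study's key pattern (significant temperature response
in tumors, not in normals) instead of the wildly overpowered contrasts
that independent or perfectly-coupled endpoint draws would produce.

Between the endpoints, resistivities follow a geometric (log-linear)
temperature dependence with the per-sample fold ratio as the only shape
parameter, and thermal conductivity interpolates linearly.

Forward measurement model
-------------------------
At setpoint T the heater chip face is at T and the opposite (sink) chip is
coupled to ambient through a fixed sink conductance, so the steady state is
series conduction: ``Q = (k A / l) * (T - T_sink) = G_sink * (T_sink -
T_amb)``.  Raw observables are the bulk resistance ``R_B = rho_B l / A_el``,
two surface resistances ``R_s = rho_S / g`` (one per chip), the heater
voltage/current split by a precalibrated voltage-temperature map, and three
sink RTD resistances.  Multiplicative Gaussian noise with a common
coefficient of variation is applied independently to every observable; for
the RTDs the relative error is applied to the measured temperature drop
(the physically meaningful instrument error) and converted to resistance
exactly.  With ``noise_cv = 0`` the inverse pipeline recovers the ground
truth to machine precision.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from . import reference
from .chip_model import ChipGeometry, RTDCalibration, geometric_factor, temperature_to_resistance
from .errors import InvalidParametersError, ProtocolError

__all__ = [
    "GroupParameters",
    "SampleGeometry",
    "TissueTruth",
    "StudyConfig",
    "MeasurementRecord",
    "GEOMETRY_TOLERANCES_MM",
    "default_group_parameters",
    "group_parameters",
    "sample_tissue_truth",
    "forward_measurements",
    "generate_study",
    "truth_frame_row",
    "truth_from_row",
]

#: Machining tolerances of the cubical sample blocks (mm): +/- on the two
#: 5 mm sides and on the 3 mm thickness.
GEOMETRY_TOLERANCES_MM = (0.15, 0.23, 0.13)

_PREP_CODE = {"deparaffinized": "SP", "formalin_fixed": "SF"}


@dataclass(frozen=True)
class GroupParameters:
    """Published summary statistics of one group-by-preparation cell.

    Means/spreads are in reporting units (rho_b: ohm cm, rho_s: ohm/sq,
    k: W m^-1 K^-1); spreads are SEMs over ``n_cell`` samples.  The
    ``p_temp_*`` entries are the published paired-t p-values of the
    37-vs-25 contrast, used to calibrate the within-sample endpoint
    correlation (``None`` means uncorrelated endpoints).
    """

    group: str
    preparation: str
    rho_b_25_mean: float
    rho_b_25_spread: float
    rho_b_37_mean: float
    rho_b_37_spread: float
    rho_s_25_mean: float
    rho_s_25_spread: float
    rho_s_37_mean: float
    rho_s_37_spread: float
    k_25_mean: float
    k_25_spread: float
    k_37_mean: float
    k_37_spread: float
    p_temp_rho_b: float | None = None
    p_temp_rho_s: float | None = None
    p_temp_k: float | None = None
    n_cell: int = reference.N_PER_CELL

    def __post_init__(self) -> None:
        for name in (
            "rho_b_25_mean", "rho_b_37_mean", "rho_s_25_mean", "rho_s_37_mean",
            "k_25_mean", "k_37_mean",
        ):
            if getattr(self, name) <= 0.0:
                raise InvalidParametersError(f"{name} must be > 0")
        for name in (
            "rho_b_25_spread", "rho_b_37_spread", "rho_s_25_spread",
            "rho_s_37_spread", "k_25_spread", "k_37_spread",
        ):
            if getattr(self, name) < 0.0:
                raise InvalidParametersError(f"{name} must be >= 0")

    # Fold ratios (37 deg C mean over 25 deg C mean), as tabulated.
    @property
    def fold_rho_b(self) -> float:
        return self.rho_b_37_mean / self.rho_b_25_mean

    @property
    def fold_rho_s(self) -> float:
        return self.rho_s_37_mean / self.rho_s_25_mean

    @property
    def fold_k(self) -> float:
        return self.k_37_mean / self.k_25_mean

    def endpoint_summary(self, parameter: str) -> tuple[float, float, float, float, float | None]:
        """(mean25, spread25, mean37, spread37, p_temp) for one parameter."""
        return (
            getattr(self, f"{parameter}_25_mean"),
            getattr(self, f"{parameter}_25_spread"),
            getattr(self, f"{parameter}_37_mean"),
            getattr(self, f"{parameter}_37_spread"),
            getattr(self, f"p_temp_{parameter}"),
        )


def default_group_parameters() -> list[GroupParameters]:
    """The four group-by-preparation cells of the reference cohort."""
    out = []
    for (prep, group), table in reference.GROUP_SUMMARY.items():
        contrast = "T37_vs_T25" if group == "tumor" else "N37_vs_N25"
        pvals = reference.SINGLE_PARAMETER_P[prep][contrast]
        kwargs: dict[str, float] = {}
        for param in reference.PARAMETERS:
            m25, s25, m37, s37 = table[param]
            kwargs[f"{param}_25_mean"] = m25
            kwargs[f"{param}_25_spread"] = s25
            kwargs[f"{param}_37_mean"] = m37
            kwargs[f"{param}_37_spread"] = s37
            kwargs[f"p_temp_{param}"] = pvals[param]
        out.append(GroupParameters(group=group, preparation=prep, **kwargs))
    return out


def group_parameters(preparation: str, group: str) -> GroupParameters:
    """Look up one default cell by preparation and group label."""
    for params in default_group_parameters():
        if params.preparation == preparation and params.group == group:
            return params
    raise InvalidParametersError(f"unknown cell ({preparation!r}, {group!r})")


@dataclass(frozen=True)
class SampleGeometry:
    """Cubical tissue block: 5 x 5 mm faces, 3 mm thickness (SI metres).

    ``contact_area`` is the heat-transfer cross-section of the thermal path
    (the chip-contact face), defaulting to ``side_x * side_y``.
    """

    side_x: float = 5.0e-3
    side_y: float = 5.0e-3
    thickness: float = 3.0e-3
    contact_area: float | None = None

    def __post_init__(self) -> None:
        if min(self.side_x, self.side_y, self.thickness) <= 0.0:
            raise InvalidParametersError("sample dimensions must be > 0")
        if self.contact_area is None:
            object.__setattr__(self, "contact_area", self.side_x * self.side_y)
        if self.contact_area <= 0.0:
            raise InvalidParametersError("contact_area must be > 0")


@dataclass(frozen=True)
class TissueTruth:
    """Ground-truth electrothermal parameters of one synthetic sample.

    ``rho_b_25`` in ohm cm, ``rho_s_25`` in ohm/sq, ``k_25`` in
    W m^-1 K^-1; fold factors are the per-sample 37/25 deg C ratios.
    """

    sample_id: str
    patient_id: str
    group: str
    preparation: str
    geometry: SampleGeometry
    rho_b_25: float
    rho_s_25: float
    k_25: float
    fold_rho_b: float
    fold_rho_s: float
    fold_k: float

    def __post_init__(self) -> None:
        for name in ("rho_b_25", "rho_s_25", "k_25", "fold_rho_b", "fold_rho_s", "fold_k"):
            if getattr(self, name) <= 0.0:
                raise InvalidParametersError(f"{name} must be > 0")

    def value_at(self, parameter: str, temperature_c: float) -> float:
        """Ground-truth parameter value at a tissue temperature (deg C).

        Resistivities interpolate geometrically between the endpoints
        (``rho(T) = rho_25 * fold**((T - 25) / 12)``); k linearly.
        """
        frac = (temperature_c - 25.0) / 12.0
        if parameter in ("rho_b", "rho_s"):
            base = self.rho_b_25 if parameter == "rho_b" else self.rho_s_25
            fold = self.fold_rho_b if parameter == "rho_b" else self.fold_rho_s
            return base * fold ** frac
        if parameter == "k":
            return self.k_25 * (1.0 + (self.fold_k - 1.0) * frac)
        raise InvalidParametersError(f"unknown parameter {parameter!r}")


@dataclass(frozen=True)
class StudyConfig:
    """Design of one synthetic study (defaults = the reference design)."""

    patients_per_preparation: int = 4
    repeats_per_block: int = 3
    temperature_setpoints: tuple[float, ...] = (25.0, 28.0, 31.0, 34.0, 37.0)
    noise_cv: float = 0.02
    seed: int = 0
    chip: ChipGeometry = field(default_factory=ChipGeometry)
    calib: RTDCalibration = field(default_factory=RTDCalibration)
    preparations: tuple[str, ...] = ("deparaffinized", "formalin_fixed")
    #: Ambient temperature the sink chip leaks to (deg C) and its thermal
    #: conductance (W/K); together they set the steady-state sink reading.
    t_ambient: float = 20.0
    sink_conductance: float = 0.01
    #: Precalibrated heater voltage map V(T) = v0 + v_slope * (T - 25).
    heater_v0: float = 0.8
    heater_v_slope: float = 0.15

    def __post_init__(self) -> None:
        if self.patients_per_preparation < 1 or self.repeats_per_block < 1:
            raise InvalidParametersError("need at least one patient and one repeat")
        if self.noise_cv < 0.0:
            raise InvalidParametersError("noise_cv must be >= 0")
        if not self.temperature_setpoints:
            raise InvalidParametersError("need at least one setpoint")
        for t in self.temperature_setpoints:
            if not (25.0 <= t <= 37.0):
                raise ProtocolError(
                    f"setpoint {t} outside the 25-37 deg C protocol range "
                    "(tissue collagen is thermally unstable beyond 37 deg C)"
                )
        if self.sink_conductance <= 0.0:
            raise InvalidParametersError("sink_conductance must be > 0")
        if self.t_ambient >= min(self.temperature_setpoints):
            raise InvalidParametersError(
                "ambient must sit below the lowest setpoint for a positive gradient"
            )


@dataclass(frozen=True)
class MeasurementRecord:
    """Raw observables of one sample at one temperature setpoint."""

    sample_id: str
    patient_id: str
    group: str
    preparation: str
    setpoint_c: float
    r_bulk_ohm: float
    r_surf1_ohm: float
    r_surf2_ohm: float
    heater_v: float
    heater_i: float
    rtd1_ohm: float
    rtd2_ohm: float
    rtd3_ohm: float
    t_source_c: float

    @property
    def rtd_resistances(self) -> tuple[float, float, float]:
        return (self.rtd1_ohm, self.rtd2_ohm, self.rtd3_ohm)


# ---------------------------------------------------------------------------
# Sampling


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and SD (moment match)."""
    if sd == 0.0:
        return math.log(mean), 0.0
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


@functools.lru_cache(maxsize=None)
def _calibrated_log_rho(
    mu1: float, sg1: float, mu2: float, sg2: float,
    p_paired: float, n_cell: int,
) -> float:
    """Log-space endpoint correlation matching a published paired-t p-value.

    The endpoints of one sample are a bivariate lognormal; their
    correlation governs the spread of the paired 37-minus-25 differences
    and hence the paired-t statistic of an n_cell cohort.  Because the
    differences are strongly skewed, a moment identity misstates the
    typical realised t, so the correlation is calibrated numerically:
    bisection on rho until the *median* simulated paired-t p (400
    common-random-number cohorts, fixed internal seed) matches the
    published p.  Clamped to +/-0.999 when the target is unreachable.
    Deterministic and cached per parameter cell.
    """
    rng = np.random.default_rng(1_234_567)
    z1 = rng.standard_normal((400, n_cell))
    zr = rng.standard_normal((400, n_cell))

    def median_p(rho: float) -> float:
        z2 = rho * z1 + math.sqrt(1.0 - rho**2) * zr
        d = np.exp(mu2 + sg2 * z2) - np.exp(mu1 + sg1 * z1)
        sd = d.std(axis=1, ddof=1)
        sd[sd == 0.0] = np.inf
        t = d.mean(axis=1) / (sd / math.sqrt(n_cell))
        return float(np.median(2.0 * stats.t.sf(np.abs(t), n_cell - 1)))

    lo, hi = -0.999, 0.999
    if median_p(lo) <= p_paired:  # even maximal diff spread too significant
        return lo
    if median_p(hi) >= p_paired:
        return hi
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if median_p(mid) > p_paired:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _draw_endpoints(
    m25: float, sem25: float, m37: float, sem37: float,
    p_paired: float | None, n_cell: int, rng: np.random.Generator,
) -> tuple[float, float]:
    """One correlated (value25, value37) draw for a single parameter."""
    if sem25 < 0.0 or sem37 < 0.0:
        raise InvalidParametersError("spreads must be >= 0")
    s25 = sem25 * math.sqrt(n_cell)
    s37 = sem37 * math.sqrt(n_cell)
    mu1, sg1 = _lognormal_params(m25, s25)
    mu2, sg2 = _lognormal_params(m37, s37)
    if sg1 == 0.0 or sg2 == 0.0 or p_paired is None:
        z1, z2 = rng.standard_normal(2)
        return math.exp(mu1 + sg1 * z1), math.exp(mu2 + sg2 * z2)
    rho = _calibrated_log_rho(mu1, sg1, mu2, sg2, p_paired, n_cell)
    z1 = rng.standard_normal()
    z2 = rho * z1 + math.sqrt(1.0 - rho**2) * rng.standard_normal()
    return math.exp(mu1 + sg1 * z1), math.exp(mu2 + sg2 * z2)


def sample_tissue_truth(
    params: GroupParameters,
    rng: np.random.Generator,
    sample_id: str = "S1",
    patient_id: str = "P1",
    geometry_tolerances_mm: tuple[float, float, float] = GEOMETRY_TOLERANCES_MM,
) -> TissueTruth:
    """Draw one sample's ground truth from a group's distribution.

    Geometry is drawn uniformly within the stated machining tolerances of
    the nominal 5 x 5 x 3 mm block.  Draw order is fixed (rho_b, rho_s, k,
    then geometry) so a seeded generator reproduces cohorts exactly.
    """
    values: dict[str, float] = {}
    for param in reference.PARAMETERS:
        m25, sem25, m37, sem37, p_temp = params.endpoint_summary(param)
        v25, v37 = _draw_endpoints(m25, sem25, m37, sem37, p_temp, params.n_cell, rng)
        values[f"{param}_25"] = v25
        values[f"fold_{param}"] = v37 / v25
    tol = [t * 1e-3 for t in geometry_tolerances_mm]
    geometry = SampleGeometry(
        side_x=rng.uniform(5.0e-3 - tol[0], 5.0e-3 + tol[0]),
        side_y=rng.uniform(5.0e-3 - tol[1], 5.0e-3 + tol[1]),
        thickness=rng.uniform(3.0e-3 - tol[2], 3.0e-3 + tol[2]),
    )
    return TissueTruth(
        sample_id=sample_id,
        patient_id=patient_id,
        group=params.group,
        preparation=params.preparation,
        geometry=geometry,
        rho_b_25=values["rho_b_25"],
        rho_s_25=values["rho_s_25"],
        k_25=values["k_25"],
        fold_rho_b=values["fold_rho_b"],
        fold_rho_s=values["fold_rho_s"],
        fold_k=values["fold_k"],
    )


# ---------------------------------------------------------------------------
# Forward model


def _steady_state_thermal(
    k: float, geometry: SampleGeometry, t_source: float, config: StudyConfig
) -> tuple[float, float]:
    """(sink temperature deg C, heater power W) of the series-conduction model."""
    g_tissue = k * geometry.contact_area / geometry.thickness
    g_sink = config.sink_conductance
    t_sink = (g_tissue * t_source + g_sink * config.t_ambient) / (g_tissue + g_sink)
    q = g_tissue * (t_source - t_sink)
    return t_sink, q


def forward_measurements(
    truth: TissueTruth,
    config: StudyConfig,
    rng: np.random.Generator | None = None,
) -> list[MeasurementRecord]:
    """Simulate the raw measurement records of one sample (one per setpoint)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cv = config.noise_cv

    def jitter() -> float:
        return 1.0 + cv * rng.standard_normal() if cv > 0.0 else 1.0

    gfac = geometric_factor(config.chip)
    records = []
    for t_set in sorted(config.temperature_setpoints):
        if not (25.0 <= t_set <= 37.0):
            raise ProtocolError(f"setpoint {t_set} outside protocol range")
        rho_b_si = truth.value_at("rho_b", t_set) / 100.0  # ohm cm -> ohm m
        rho_s = truth.value_at("rho_s", t_set)
        k = truth.value_at("k", t_set)

        r_bulk = rho_b_si * truth.geometry.thickness / config.chip.electrode_area
        r_surf = rho_s / gfac
        t_sink, q = _steady_state_thermal(k, truth.geometry, t_set, config)
        v = config.heater_v0 + config.heater_v_slope * (t_set - 25.0)
        i = q / v

        # Per-RTD sink readings: relative instrument error on the measured
        # temperature drop, converted to resistance through the exact law.
        delta_t = t_set - t_sink
        rtd_ohms = [
            temperature_to_resistance(t_set - delta_t * jitter(), config.calib)
            for _ in range(3)
        ]
        records.append(
            MeasurementRecord(
                sample_id=truth.sample_id,
                patient_id=truth.patient_id,
                group=truth.group,
                preparation=truth.preparation,
                setpoint_c=float(t_set),
                r_bulk_ohm=r_bulk * jitter(),
                r_surf1_ohm=r_surf * jitter(),
                r_surf2_ohm=r_surf * jitter(),
                heater_v=v * jitter(),
                heater_i=i * jitter(),
                rtd1_ohm=rtd_ohms[0],
                rtd2_ohm=rtd_ohms[1],
                rtd3_ohm=rtd_ohms[2],
                t_source_c=float(t_set),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Cohort assembly


def truth_frame_row(truth: TissueTruth) -> dict:
    """Flatten one TissueTruth into a CSV-friendly row (mm / mm^2 geometry)."""
    g = truth.geometry
    return {
        "sample_id": truth.sample_id,
        "patient_id": truth.patient_id,
        "group": truth.group,
        "preparation": truth.preparation,
        "side_x_mm": g.side_x * 1e3,
        "side_y_mm": g.side_y * 1e3,
        "thickness_mm": g.thickness * 1e3,
        "contact_area_mm2": g.contact_area * 1e6,
        "rho_b_25_ohm_cm": truth.rho_b_25,
        "rho_s_25_ohm_sq": truth.rho_s_25,
        "k_25_w_m_k": truth.k_25,
        "fold_rho_b": truth.fold_rho_b,
        "fold_rho_s": truth.fold_rho_s,
        "fold_k": truth.fold_k,
    }


def truth_from_row(row) -> TissueTruth:
    """Rebuild a TissueTruth from a truth-table row (inverse of truth_frame_row)."""
    geometry = SampleGeometry(
        side_x=row["side_x_mm"] * 1e-3,
        side_y=row["side_y_mm"] * 1e-3,
        thickness=row["thickness_mm"] * 1e-3,
        contact_area=row["contact_area_mm2"] * 1e-6,
    )
    return TissueTruth(
        sample_id=row["sample_id"],
        patient_id=row["patient_id"],
        group=row["group"],
        preparation=row["preparation"],
        geometry=geometry,
        rho_b_25=row["rho_b_25_ohm_cm"],
        rho_s_25=row["rho_s_25_ohm_sq"],
        k_25=row["k_25_w_m_k"],
        fold_rho_b=row["fold_rho_b"],
        fold_rho_s=row["fold_rho_s"],
        fold_k=row["fold_k"],
    )


def generate_study(config: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic study: (truth table, measurement table).

    The default configuration yields 48 samples (4 patients x 2
    preparations x paired tumor/normal x 3 technical repeats) and one
    measurement record per sample per setpoint (240 rows).  All draws flow
    from a single seeded generator in a fixed order, so equal seeds give
    identical tables.
    """
    rng = np.random.default_rng(config.seed)
    truth_rows: list[dict] = []
    meas_rows: list[dict] = []
    for prep in config.preparations:
        code = _PREP_CODE.get(prep, prep[:2].upper())
        for p in range(1, config.patients_per_preparation + 1):
            patient_id = f"{code}{p}"
            for group, gcode in (("tumor", "T"), ("normal", "N")):
                params = group_parameters(prep, group)
                for r in range(1, config.repeats_per_block + 1):
                    sample_id = f"{patient_id}-{gcode}-r{r}"
                    truth = sample_tissue_truth(
                        params, rng, sample_id=sample_id, patient_id=patient_id
                    )
                    truth_rows.append(truth_frame_row(truth))
                    for rec in forward_measurements(truth, config, rng):
                        meas_rows.append(rec.__dict__.copy())
    return pd.DataFrame(truth_rows), pd.DataFrame(meas_rows)
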
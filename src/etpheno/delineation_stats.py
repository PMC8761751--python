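"""Statistical delineation of tumor vs adjacent-normal tissue.

The delineation design tests each electrothermal parameter (rho_B, rho_S,
k) across four contrasts per preparation:

* ``N37_vs_N25`` / ``T37_vs_T25`` — paired two-tailed t tests of the same
  samples at the two tissue temperatures;
* ``T25_vs_N25`` / ``T37_vs_N37`` — unpaired two-tailed t tests with the
  Welch unequal-variance correction between groups at fixed temperature.

Parameter combinations are scored with Fisher's combined probability
test: ``chi2 = -2 * sum(ln p_i)`` referred to the chi-square upper tail
with ``2 m`` degrees of freedom.  A combination cell is always derived
from the single-parameter p-values of the same column, never recomputed
from raw data.  p-values are reported raw (no multiple-testing
correction by default, matching the original analysis; a Bonferroni
option is exposed).

The module also provides the published-summary mode (combining the
published single-parameter p-values directly, which reproduces the
published combination cells without raw data), fold-change and pairwise
regression descriptors, and the two-temperature classification rule that
calls a lone sample tumor or normal from its own resistivity response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import reference
from .errors import DegenerateFitError, InputError, InvalidParametersError
from .inference import ElectrothermalProfile

__all__ = [
    "PARAMETER_SETS",
    "ContrastResult",
    "paired_t_test",
    "welch_t_test",
    "fold_change",
    "fisher_combined",
    "pairwise_regression",
    "significance_label",
    "delineation_table",
    "combined_from_published",
    "fold_change_table",
    "pairwise_r_squared",
    "classify_sample",
]

#: The seven parameter sets scored per contrast: three singles, all pairs,
#: and the full triple.
PARAMETER_SETS: tuple[tuple[str, ...], ...] = (
    ("rho_b",),
    ("rho_s",),
    ("k",),
    ("rho_b", "rho_s"),
    ("rho_b", "k"),
    ("rho_s", "k"),
    ("rho_b", "rho_s", "k"),
)


def set_label(params: Sequence[str]) -> str:
    return "+".join(params)


@dataclass(frozen=True)
class ContrastResult:
    """One cell of the delineation table."""

    preparation: str
    parameter_set: str
    contrast: str
    p_value: float
    label: str
    test: str


# ---------------------------------------------------------------------------
# Elementary tests


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Classical paired two-tailed t test; returns (t, df, p).

    Degenerate difference variance is handled explicitly: all-zero
    differences give p = 1; a constant nonzero difference is an infinitely
    strong effect and gives p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("paired test needs two equal-length 1-D samples")
    n = x.size
    if n < 2:
        raise InputError("paired test needs at least two pairs")
    d = x - y
    mean = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, mean), df, 0.0
    t = mean / (sd / math.sqrt(n))
    return float(t), df, float(2.0 * stats.t.sf(abs(t), df))


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Unpaired two-tailed t test with the Welch unequal-variance correction.

    Returns (t, Welch-Satterthwaite df, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size < 2 or y.size < 2:
        raise InputError("each group needs at least two observations")
    n1, n2 = x.size, y.size
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0.0:
        df = float(n1 + n2 - 2)
        if x.mean() == y.mean():
            return 0.0, df, 1.0
        return math.copysign(math.inf, x.mean() - y.mean()), df, 0.0
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return float(t), float(df), float(2.0 * stats.t.sf(abs(t), df))


def fold_change(value_hi: float, value_lo: float) -> float:
    """Ratio ``value_hi / value_lo`` (e.g. the 37 / 25 deg C group means)."""
    if value_lo <= 0.0:
        raise InvalidParametersError(f"fold-change denominator must be > 0, got {value_lo!r}")
    return value_hi / value_lo


def fisher_combined(p_values: Sequence[float]) -> float:
    """Fisher's combined probability: chi2 = -2 sum ln p_i, df = 2 m.

    Exchangeable in its inputs, monotone (smaller inputs give a smaller
    combination), and the identity map for m = 1.
    """
    ps = np.asarray(p_values, dtype=float)
    if ps.ndim != 1 or ps.size < 1:
        raise InputError("need at least one p-value")
    if np.any(ps <= 0.0) or np.any(ps > 1.0):
        raise InvalidParametersError("p-values must lie in (0, 1]")
    chi2 = -2.0 * np.log(ps).sum()
    return float(stats.chi2.sf(chi2, df=2 * ps.size))


def pairwise_regression(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Ordinary least-squares line of y on x; returns (slope, intercept, R^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise InputError("regression needs at least three aligned points")
    if x.var() == 0.0:
        raise DegenerateFitError("zero variance in x: regression line undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def significance_label(p: float) -> str:
    """Star label: *** p<0.001, ** p<0.01, * p<0.05, ns otherwise.

    Exact band boundaries (p = 0.001, 0.01, 0.05) fall in the less
    significant band.
    """
    if not (0.0 < p <= 1.0):
        raise InvalidParametersError(f"p must lie in (0, 1], got {p!r}")
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 5e-2:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# Delineation table


def _assemble_table(
    singles: Mapping[str, Mapping[str, float]],
    preparation: str,
    single_test: Mapping[str, str] | None = None,
    correction: bool = False,
) -> list[ContrastResult]:
    """Build the 7-set x 4-contrast cells from single-parameter p-values.

    ``singles[contrast][parameter]`` may be NaN for a flagged gap; any
    combination touching a gap is itself flagged (NaN, label ``na``).
    """
    n_tests = sum(
        1 for c in reference.CONTRASTS for p in reference.PARAMETERS
        if np.isfinite(singles.get(c, {}).get(p, math.nan))
    )
    out: list[ContrastResult] = []
    for contrast in reference.CONTRASTS:
        by_param = singles.get(contrast, {})
        for params in PARAMETER_SETS:
            ps = [by_param.get(p, math.nan) for p in params]
            if any(not np.isfinite(p) for p in ps):
                p_comb, label = math.nan, "na"
            elif len(params) == 1:
                p_comb = ps[0]
                if correction:
                    p_comb = min(1.0, p_comb * n_tests)
                label = significance_label(p_comb)
            else:
                p_comb = fisher_combined(ps)
                label = significance_label(p_comb)
            test = (
                "fisher" if len(params) > 1
                else (single_test or {}).get(contrast, "paired" if "25" in contrast and "37" in contrast else "")
            )
            out.append(
                ContrastResult(
                    preparation=preparation,
                    parameter_set=set_label(params),
                    contrast=contrast,
                    p_value=p_comb,
                    label=label,
                    test=test,
                )
            )
    return out


_SINGLE_TEST = {
    "N37_vs_N25": "paired",
    "T37_vs_T25": "paired",
    "T25_vs_N25": "welch",
    "T37_vs_N37": "welch",
}


def _endpoint_values(frame: pd.DataFrame, group: str, temperature: float, param: str) -> pd.Series:
    sub = frame[(frame["group"] == group) & (frame["temperature_c"] == temperature)]
    return sub.set_index("sample_id")[_PARAM_COL[param]].dropna()


_PARAM_COL = {"rho_b": "rho_b_ohm_cm", "rho_s": "rho_s_ohm_sq", "k": "k_w_m_k"}


def delineation_table(
    profiles: pd.DataFrame | Iterable[ElectrothermalProfile],
    correction: bool = False,
) -> pd.DataFrame:
    """Full delineation table from inferred profiles.

    ``profiles`` is either a tidy profile frame (see
    :func:`etpheno.inference.profiles_to_frame`) or an iterable of
    :class:`ElectrothermalProfile`.  Only the 25 and 37 deg C entries enter
    the analysis (the endpoints the study reports); intermediate setpoints
    are ignored here but retained in the profiles.

    Returns one row per preparation x parameter-set x contrast (28 cells
    per preparation).  A contrast whose group is absent is flagged with a
    NaN p-value and the ``na`` label, as are the combinations built on it.
    """
    if not isinstance(profiles, pd.DataFrame):
        from .inference import profiles_to_frame

        profiles = profiles_to_frame(profiles)
    rows: list[ContrastResult] = []
    for prep, frame in profiles.groupby("preparation", sort=True):
        singles: dict[str, dict[str, float]] = {c: {} for c in reference.CONTRASTS}
        for param in reference.PARAMETERS:
            n25 = _endpoint_values(frame, "normal", 25.0, param)
            n37 = _endpoint_values(frame, "normal", 37.0, param)
            t25 = _endpoint_values(frame, "tumor", 25.0, param)
            t37 = _endpoint_values(frame, "tumor", 37.0, param)

            def _paired(a: pd.Series, b: pd.Series) -> float:
                common = a.index.intersection(b.index)
                if len(common) < 2:
                    return math.nan
                return paired_t_test(a.loc[common].to_numpy(), b.loc[common].to_numpy())[2]

            def _welch(a: pd.Series, b: pd.Series) -> float:
                if len(a) < 2 or len(b) < 2:
                    return math.nan
                return welch_t_test(a.to_numpy(), b.to_numpy())[2]

            singles["N37_vs_N25"][param] = _paired(n37, n25)
            singles["T37_vs_T25"][param] = _paired(t37, t25)
            singles["T25_vs_N25"][param] = _welch(t25, n25)
            singles["T37_vs_N37"][param] = _welch(t37, n37)
        rows.extend(_assemble_table(singles, str(prep), _SINGLE_TEST, correction))
    return pd.DataFrame([r.__dict__ for r in rows])


def combined_from_published(p_frame: pd.DataFrame | None = None) -> pd.DataFrame:
    """Delineation table assembled from published single-parameter p-values.

    This is the summary-input mode: with no raw per-sample data, the
    published per-parameter p-values are taken as given and only the
    Fisher combinations are computed.  With the default input table the
    combination cells reproduce the published ones to the printed
    precision.
    """
    if p_frame is None:
        p_frame = reference.single_parameter_p_frame()
    required = {"preparation", "contrast", "parameter", "p_value"}
    if not required.issubset(p_frame.columns):
        raise InputError(f"summary table needs columns {sorted(required)}")
    rows: list[ContrastResult] = []
    for prep, frame in p_frame.groupby("preparation", sort=True):
        singles: dict[str, dict[str, float]] = {c: {} for c in reference.CONTRASTS}
        for rec in frame.itertuples():
            singles.setdefault(rec.contrast, {})[rec.parameter] = rec.p_value
        rows.extend(_assemble_table(singles, str(prep), _SINGLE_TEST))
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# Descriptive outputs (fold changes, pairwise regression)


def fold_change_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Group-mean fold change (37 over 25 deg C) per preparation and parameter."""
    rows = []
    for (prep, group), frame in profiles.groupby(["preparation", "group"], sort=True):
        for param, col in _PARAM_COL.items():
            m25 = frame.loc[frame["temperature_c"] == 25.0, col].mean()
            m37 = frame.loc[frame["temperature_c"] == 37.0, col].mean()
            rows.append(
                {
                    "preparation": prep,
                    "group": group,
                    "parameter": param,
                    "mean_25": m25,
                    "mean_37": m37,
                    "fold_37_over_25": fold_change(m37, m25),
                }
            )
    return pd.DataFrame(rows)


def pairwise_r_squared(profiles: pd.DataFrame, per_preparation: bool = True) -> pd.DataFrame:
    """Pairwise OLS R^2 between parameters, per group (tumor / normal).

    Low R^2 indicates the parameters carry independent delineation
    information.  Values at both endpoint temperatures are pooled; rows
    are produced per preparation and pooled across preparations.
    """
    pairs = (("rho_b", "k"), ("rho_s", "k"), ("rho_s", "rho_b"))
    endpoints = profiles[profiles["temperature_c"].isin([25.0, 37.0])]
    scopes: list[tuple[str, pd.DataFrame]] = [("pooled", endpoints)]
    if per_preparation:
        scopes += [(str(p), f) for p, f in endpoints.groupby("preparation", sort=True)]
    rows = []
    for scope, frame in scopes:
        for group, gframe in frame.groupby("group", sort=True):
            for px, py in pairs:
                x = gframe[_PARAM_COL[px]].to_numpy()
                y = gframe[_PARAM_COL[py]].to_numpy()
                ok = np.isfinite(x) & np.isfinite(y)
                if ok.sum() < 3 or x[ok].var() == 0.0:
                    continue
                slope, intercept, r2 = pairwise_regression(x[ok], y[ok])
                rows.append(
                    {
                        "scope": scope,
                        "group": group,
                        "x": px,
                        "y": py,
                        "slope": slope,
                        "intercept": intercept,
                        "r_squared": r2,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Two-temperature classification rule


def classify_sample(
    repeats: Sequence[ElectrothermalProfile],
    alpha: float = 0.05,
    fold_threshold: float = 3.8,
) -> tuple[str, dict]:
    """Call one specimen tumor or normal from its own temperature response.

    The rule needs no adjacent-normal reference: tumors show a
    significantly larger resistivity rise from 25 to 37 deg C.  A tumor is
    called when, across the technical repeats, the paired 25 -> 37 deg C
    increase is significant at ``alpha`` for both rho_B and rho_S *and*
    both mean fold changes exceed ``fold_threshold``.  The default
    threshold 3.8 sits midway between the reported tumor (~4.1-4.8) and
    normal (~2.9-3.5) fold ranges.

    Returns ``(call, evidence)`` where evidence holds the per-parameter
    p-values and fold changes.
    """
    if len(repeats) < 2:
        raise InputError("need at least two technical repeats to classify")
    evidence: dict = {}
    votes = []
    for param in ("rho_b", "rho_s"):
        try:
            v25 = np.array([getattr(p.at(25.0), _ENTRY_ATTR[param]) for p in repeats])
            v37 = np.array([getattr(p.at(37.0), _ENTRY_ATTR[param]) for p in repeats])
        except KeyError as exc:
            raise InputError(f"classification needs both endpoint temperatures: {exc}") from exc
        if not (np.isfinite(v25).all() and np.isfinite(v37).all()):
            raise InputError("classification needs complete endpoint measurements")
        _, _, p = paired_t_test(v37, v25)
        fold = fold_change(float(v37.mean()), float(v25.mean()))
        evidence[f"p_{param}"] = p
        evidence[f"fold_{param}"] = fold
        votes.append(p < alpha and fold > fold_threshold)
    call = "tumor" if all(votes) else "normal"
    evidence["alpha"] = alpha
    evidence["fold_threshold"] = fold_threshold
    return call, evidence


_ENTRY_ATTR = {"rho_b": "rho_b_ohm_cm", "rho_s": "rho_s_ohm_sq", "k": "k_w_m_k"}


def classification_benchmark(
    n_per_class: int = 100,
    preparation: str = "formalin_fixed",
    noise_cv: float = 0.02,
    repeats: int = 3,
    seed: int = 0,
    alpha: float = 0.05,
    fold_threshold: float = 3.8,
) -> dict:
    """Sensitivity/specificity of the two-temperature rule under noise.

    Each replicate is a specimen whose true parameters sit at its group's
    published means (fold = the group fold ratio); ``repeats`` technical
    repeats are forward-simulated at the two endpoint temperatures with
    multiplicative measurement noise and classified.  This isolates the
    rule's robustness to instrument noise from inter-patient biological
    spread (which the published summaries leave underdetermined).
    """
    from .inference import build_profile
    from .synthetic_study import (
        SampleGeometry,
        StudyConfig,
        TissueTruth,
        forward_measurements,
        group_parameters,
    )

    rng = np.random.default_rng(seed)
    config = StudyConfig(
        temperature_setpoints=(25.0, 37.0), noise_cv=noise_cv, seed=seed
    )
    counts = {"tumor": {"tumor": 0, "normal": 0}, "normal": {"tumor": 0, "normal": 0}}
    for group in ("tumor", "normal"):
        gp = group_parameters(preparation, group)
        for i in range(n_per_class):
            profiles = []
            for r in range(repeats):
                truth = TissueTruth(
                    sample_id=f"{group}{i}-r{r}",
                    patient_id=f"{group}{i}",
                    group=group,
                    preparation=preparation,
                    geometry=SampleGeometry(),
                    rho_b_25=gp.rho_b_25_mean,
                    rho_s_25=gp.rho_s_25_mean,
                    k_25=gp.k_25_mean,
                    fold_rho_b=gp.fold_rho_b,
                    fold_rho_s=gp.fold_rho_s,
                    fold_k=gp.fold_k,
                )
                records = forward_measurements(truth, config, rng)
                profiles.append(
                    build_profile(records, config.chip, config.calib, truth.geometry)
                )
            call, _ = classify_sample(profiles, alpha=alpha, fold_threshold=fold_threshold)
            counts[group][call] += 1
    sens = counts["tumor"]["tumor"] / n_per_class
    spec = counts["normal"]["normal"] / n_per_class
    return {"sensitivity": sens, "specificity": spec, "counts": counts}
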
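"""Published group-level summaries of the reference breast-biopsy cohort.

The original ex vivo study measured paired tumor / adjacent-normal breast
biopsy blocks from N = 8 patients (4 formalin-fixed, 4 deparaffinized FFPE;
3 technical repeats per block, i.e. 12 samples per group-by-preparation
cell) at tissue temperatures of 25 and 37 deg C.  Per-sample raw data were
not deposited; what is public are the group means with a +/- spread for
bulk resistivity rho_B (ohm cm), surface resistivity rho_S (ohm per
square) and thermal conductivity k (W m^-1 K^-1), the paired-t p-values
for the 37-vs-25 temperature contrast inside each group, and the full
matrix of single-parameter p-values for the four delineation contrasts.

These tables are the parameterisation of the synthetic-cohort generator
and the input to the summary (published p-value) mode of the delineation
statistics.  The "+/-" spreads are treated as standard errors of the mean
with n = 12 per cell (the study does not say SD or SEM; this is a declared
modelling assumption, see docs/methods.md).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "N_PER_CELL",
    "GROUP_SUMMARY",
    "SINGLE_PARAMETER_P",
    "CONTRASTS",
    "PARAMETERS",
    "PREPARATIONS",
    "single_parameter_p_frame",
]

#: Samples per group-by-preparation cell (4 patients x 3 technical repeats).
N_PER_CELL = 12

PREPARATIONS = ("deparaffinized", "formalin_fixed")
PARAMETERS = ("rho_b", "rho_s", "k")
#: Delineation contrasts: within-group across temperature (paired) and
#: between-group at fixed temperature (Welch).
CONTRASTS = ("N37_vs_N25", "T37_vs_T25", "T25_vs_N25", "T37_vs_N37")

# (preparation, group) -> parameter -> (mean25, spread25, mean37, spread37)
# rho_b in ohm cm, rho_s in ohm/sq, k in W m^-1 K^-1.
GROUP_SUMMARY: dict[tuple[str, str], dict[str, tuple[float, float, float, float]]] = {
    ("deparaffinized", "normal"): {
        "rho_b": (148.42, 76.44, 456.09, 194.63),
        "rho_s": (221.24, 74.71, 648.2, 419.44),
        "k": (0.456, 0.023, 0.47, 0.018),
    },
    ("deparaffinized", "tumor"): {
        "rho_b": (411.25, 172.03, 1980.87, 185.00),
        "rho_s": (753.05, 292.05, 3131.88, 638.18),
        "k": (0.207, 0.023, 0.255, 0.0255),
    },
    ("formalin_fixed", "normal"): {
        "rho_b": (56.39, 10.4, 195.70, 62.19),
        "rho_s": (160.5, 24.25, 484.97, 159.81),
        "k": (0.563, 0.028, 0.599, 0.022),
    },
    ("formalin_fixed", "tumor"): {
        "rho_b": (224.125, 61.72, 991.4, 152.92),
        "rho_s": (507.08, 162.19, 2095.07, 116.83),
        "k": (0.309, 0.02, 0.335, 0.0206),
    },
}

# preparation -> contrast -> parameter -> published p-value.
SINGLE_PARAMETER_P: dict[str, dict[str, dict[str, float]]] = {
    "deparaffinized": {
        "N37_vs_N25": {"rho_b": 1.03e-1, "rho_s": 3.05e-1, "k": 2.94e-1},
        "T37_vs_T25": {"rho_b": 1.15e-3, "rho_s": 8e-3, "k": 5.15e-3},
        "T25_vs_N25": {"rho_b": 2.33e-1, "rho_s": 1.65e-1, "k": 6.02e-4},
        "T37_vs_N37": {"rho_b": 1.3e-3, "rho_s": 2.15e-2, "k": 1.49e-3},
    },
    "formalin_fixed": {
        "N37_vs_N25": {"rho_b": 9.57e-2, "rho_s": 1.43e-1, "k": 2.14e-2},
        "T37_vs_T25": {"rho_b": 1.4e-2, "rho_s": 7.44e-3, "k": 6e-3},
        "T25_vs_N25": {"rho_b": 7e-2, "rho_s": 1.21e-1, "k": 1.03e-3},
        "T37_vs_N37": {"rho_b": 8.7e-3, "rho_s": 2.89e-4, "k": 3.21e-4},
    },
}


def single_parameter_p_frame() -> pd.DataFrame:
    """The published single-parameter p-values as a tidy DataFrame.

    Columns: preparation, contrast, parameter, p_value.
    """
    rows = [
        {"preparation": prep, "contrast": contrast, "parameter": param, "p_value": p}
        for prep, by_contrast in SINGLE_PARAMETER_P.items()
        for contrast, by_param in by_contrast.items()
        for param, p in by_param.items()
    ]
    return pd.DataFrame(rows)
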
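"""In-study measurement tables for the Salmonella supercoil-sensor survey.

Resolution efficiencies, apparent diffusible supercoil densities and mutant
impact factors for the gamma-delta sensor inserted at ten chromosome
positions, in wild type and in temperature-sensitive gyrase / Topo IV /
RNA-polymerase mutant backgrounds, plus the rifampicin-rebound series.
Efficiencies are stored as fractions; rows below the 1% detection limit are
flagged ``censored`` and carry no point value.
"""

from __future__ import annotations

import pandas as pd

DETECTION_LIMIT = 0.01

# strain, position_cs, genotype, eff, eff_sd, censored, mif_display, sigma_d
_TABLE1 = [
    ("NH3868", 57.65, "WT", 0.75, 0.06, False, "1", -0.037),
    ("NH4028", 57.64, "WT", 0.28, 0.03, False, "1", -0.023),
    ("NH6000", 85.0, "WT", 0.81, 0.04, False, "1", -0.038),
    ("NH6001", 71.0, "WT", 0.82, 0.02, False, "1", -0.038),
    ("NH6002", 58.0, "WT", 0.80, 0.03, False, "1", -0.038),
    ("NH6003", 45.0, "WT", 0.73, 0.06, False, "1", -0.036),
    ("NH6005", 33.0, "WT", 0.45, 0.06, False, "1", -0.022),
    ("NH6006", 21.0, "WT", 0.92, 0.02, False, "1", -0.041),
    ("NH6007", 9.0, "WT", 0.73, 0.12, False, "1", -0.036),
    ("NH6008", 96.0, "WT", 0.85, 0.03, False, "1", -0.040),
    ("NH6016", 85.0, "gyrA213", 0.58, 0.01, False, "1.4", -0.032),
    ("NH6019", 85.0, "gyrA209", 0.30, 0.12, False, "3", -0.024),
    ("NH6020", 71.0, "gyrA209", 0.30, 0.06, False, "3", -0.024),
    ("NH6021", 58.0, "gyrA209", 0.26, 0.09, False, "3", -0.022),
    ("NH6022", 45.0, "gyrA209", 0.17, 0.05, False, "5", -0.018),
    ("NH6024", 33.0, "gyrA209", 0.09, 0.04, False, "5", -0.013),
    ("NH6025", 21.0, "gyrA209", 0.20, 0.13, False, "5", -0.019),
    ("NH6026", 9.0, "gyrA209", 0.30, 0.03, False, "2", -0.020),
    ("NH6027", 96.0, "gyrA209", 0.48, 0.05, False, "2", -0.030),
    ("NH6028", 85.0, "gyrB652", 0.07, 0.03, False, "12", -0.012),
    ("NH6029", 71.0, "gyrB652", None, None, True, ">80", None),
    ("NH6030", 58.0, "gyrB652", 0.02, 0.01, False, "40", -0.004),
    ("NH6031", 45.0, "gyrB652", None, None, True, ">70", None),
    ("NH6033", 33.0, "gyrB652", None, None, True, ">45", None),
    ("NH6034", 21.0, "gyrB652", None, None, True, ">90", None),
    ("NH6035", 9.0, "gyrB652", None, None, True, ">70", None),
    ("NH6036", 96.0, "gyrB652", 0.03, 0.01, False, "28", -0.007),
    ("NH6040", 85.0, "parC281", 0.76, 0.01, False, "1.1", -0.037),
    ("NH6043", 85.0, "parE206", 0.59, 0.04, False, "1.4", -0.033),
    ("NH6044", 71.0, "parE206", 0.66, 0.04, False, "1.2", -0.034),
    ("NH6045", 58.0, "parE206", 0.64, 0.03, False, "1.1", -0.034),
    ("NH6046", 45.0, "parE206", 0.60, 0.06, False, "0.8", -0.032),
    ("NH6048", 33.0, "parE206", 0.27, 0.02, False, "1.7", -0.021),
    ("NH6049", 21.0, "parE206", 0.58, 0.03, False, "1.6", -0.032),
    ("NH6056", 9.0, "parE206", 0.51, 0.04, False, "1.4", -0.030),
    ("NH6058", 96.0, "parE206", 0.63, 0.04, False, "1.3", -0.033),
]

# strain, genotype, doubling_min, doubling_sd, eff, eff_sd, sigma_d, mif_display
_TABLE2 = [
    ("NH6000", "WT", 39, 1, 0.81, 0.03, -0.038, "1"),
    ("NH6016", "gyrA213", 39, 1, 0.58, 0.01, -0.032, "1.4"),
    ("NH6019", "gyrA209", 45, 3, 0.30, 0.13, -0.026, "2.7"),
    ("NH6028", "gyrB652", 53, 3, 0.07, 0.03, -0.010, "12"),
    ("NH6037", "gyrB1820", 58, 4, 0.08, 0.06, -0.011, "10"),
    ("NH6040", "parC281", 39, 1, 0.76, 0.01, -0.037, "1.1"),
    ("NH6043", "parE206", 52, 2, 0.59, 0.04, -0.032, "1.4"),
]

# strain, position_cs, eff, eff_sd, censored, mif_display,
# eff_rif, eff_rif_sd, delta_sigma_rif
_TABLE3 = [
    ("NH6037", 85.0, 0.08, 0.06, False, "9", 0.56, 0.05, -0.020),
    ("NH6108", 71.0, None, None, True, ">80", 0.11, 0.06, -0.012),
    ("NH6109", 58.0, None, None, True, ">80", 0.57, 0.02, -0.030),
    ("NH6110", 45.0, 0.01, 0.01, False, ">73", 0.22, 0.07, -0.018),
    ("NH6111", 33.0, None, None, True, ">45", 0.02, 0.01, -0.004),
    ("NH6112", 21.0, 0.01, 0.01, False, "90", 0.19, 0.06, -0.016),
    ("NH6113", 9.0, None, None, True, ">73", 0.11, 0.02, -0.012),
    ("NH6114", 96.0, None, None, True, ">85", 0.09, 0.05, -0.011),
]

# strain, position_cs, eff, eff_sd, mif_display
_TABLE4 = [
    ("NH6206", 85.0, 0.97, 0.01, "0.83"),
    ("NH6207", 71.0, 0.86, 0.07, "0.95"),
    ("NH6208", 58.0, 0.82, 0.15, "0.98"),
    ("NH6209", 45.0, 0.92, 0.02, "0.79"),
    ("NH6210", 33.0, 0.68, 0.05, "0.66"),
    ("NH6211", 21.0, 0.86, 0.07, "1.07"),
    ("NH6212", 9.0, 0.86, 0.02, "0.84"),
    ("NH6213", 96.0, 0.88, 0.02, "0.96"),
    ("NH6214", 57.65, 0.83, 0.04, "0.90"),
    ("NH6215", 57.64, 0.69, 0.05, "0.41"),
]

# Coupled transcription/translation rates (nt/s) resolved per position by
# the induction-kinetics assay; only these four WT positions were reported
# individually, the rest enter only through the genome-wide means.
WT_ELONGATION_NT_S = {85.0: 69.0, 58.0: 62.0, 9.0: 38.0, 33.0: 56.0}
WT_ELONGATION_MEAN = 52.0   # +-10 over all positions
GYRB1820_ELONGATION_MEAN = 32.0  # +-6, 7 non-Ter positions
GYRB1820_ELONGATION_TER = 16.0   # +-2 at the dif-proximal sensor

#: Ter-macrodomain sensor occluded by MatP/FtsK/XerCD near dif.
TER_POSITION = 33.0
#: Sensors immediately flanking the rrnG operon (up/downstream pair).
RRNG_POSITIONS = (57.64, 57.65)
#: Default exclusion for genome-wide "7 position" aggregates.
DEFAULT_EXCLUDE = (TER_POSITION,) + RRNG_POSITIONS


def survey_tables() -> dict[str, pd.DataFrame]:
    """Return the transcribed study tables as DataFrames keyed table1..table4.

    Censored rows (printed "<1%") have NaN efficiency and ``censored=True``;
    the printed apparent sigma bound for those rows is "<-0.003".
    """
    t1 = pd.DataFrame(
        _TABLE1,
        columns=["strain", "position_cs", "genotype", "efficiency",
                 "efficiency_sd", "censored", "mif_display", "sigma_d"],
    )
    t1["condition"] = "none"
    t2 = pd.DataFrame(
        _TABLE2,
        columns=["strain", "genotype", "doubling_min", "doubling_sd",
                 "efficiency", "efficiency_sd", "sigma_d", "mif_display"],
    )
    t2["position_cs"] = 85.0
    t3 = pd.DataFrame(
        _TABLE3,
        columns=["strain", "position_cs", "efficiency", "efficiency_sd",
                 "censored", "mif_display", "efficiency_rif",
                 "efficiency_rif_sd", "delta_sigma_rif"],
    )
    t3["genotype"] = "gyrB1820"
    t4 = pd.DataFrame(
        _TABLE4,
        columns=["strain", "position_cs", "efficiency", "efficiency_sd",
                 "mif_display"],
    )
    t4["genotype"] = "rpoC_del215_220"
    t4["censored"] = False
    return {"table1": t1, "table2": t2, "table3": t3, "table4": t4}


def calibration_pairs(include_censored: bool = False) -> list[tuple[float, float]]:
    """(efficiency, sigma_d) pairs from table 1 for calibration fitting.

    Censored rows carry only a bound and are excluded by default.
    """
    pairs = [(eff, sig) for (_, _, _, eff, _, cens, _, sig) in _TABLE1
             if not cens]
    if include_censored:
        pairs += [(0.005, -0.003) for row in _TABLE1 if row[5]]
    return pairs


def wt_calibration_pairs() -> list[tuple[float, float]]:
    """(efficiency, sigma_d) pairs from the wild-type rows of table 1."""
    return [(eff, sig) for (_, _, gt, eff, _, cens, _, sig) in _TABLE1
            if gt == "WT" and not cens]
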
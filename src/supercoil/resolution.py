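"""Resolution-assay statistics: colony counts to efficiencies, censoring,
mutant impact factors, genome-wide aggregates and rifampicin rebounds.

A resolution measurement is the fraction of white (sensor-deleted) colonies
after a timed resolvase pulse, averaged over replicate platings.  Values
below the 1% scoring limit are censored and enter aggregates at the 0.5%
substitution.  The Mutant Impact Factor (MIF) is the wild-type efficiency
divided by the isogenic mutant's efficiency at the same position.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, delta_sigma, sigma_from_efficiency

__all__ = [
    "ResolutionReplicate", "ResolutionMeasurement", "CensoredValue",
    "AggregateSummary", "efficiency_from_counts", "censor_low", "mif",
    "format_mif", "aggregate_positions", "rif_rebound",
    "read_counts_tsv", "measurements_from_counts", "render_table_report",
]

DETECTION_LIMIT = 0.01
CENSOR_SUBSTITUTION = 0.005
MIN_COLONIES = 200
GENOTYPES = ("WT", "gyrA213", "gyrA209", "gyrB652", "gyrB1820",
             "parC281", "parE206", "rpoC_del215_220")


@dataclass(frozen=True)
class ResolutionReplicate:
    """One plating: white (deleted-sensor) colonies out of total scored."""

    white_count: int
    total_count: int

    def __post_init__(self):
        if self.total_count <= 0:
            raise ValueError("total_count must be positive")
        if not 0 <= self.white_count <= self.total_count:
            raise ValueError("white_count must be in [0, total_count]")
        if self.total_count < MIN_COLONIES:
            warnings.warn(
                f"only {self.total_count} colonies scored; protocol calls "
                f"for >= {MIN_COLONIES}", stacklevel=3)

    @property
    def fraction(self) -> float:
        return self.white_count / self.total_count


@dataclass
class ResolutionMeasurement:
    """Replicate resolution assays for one strain/position/condition."""

    strain_id: str
    position: float                  # centisome in [0, 100), circular
    genotype: str
    replicates: list[ResolutionReplicate]
    condition: str = "none"          # "none" | "rif"
    efficiency_mean: float = field(init=False)
    efficiency_sd: float = field(init=False)

    def __post_init__(self):
        if not 0.0 <= self.position < 100.0:
            raise ValueError("position must be a centisome in [0, 100)")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.condition not in ("none", "rif"):
            raise ValueError("condition must be 'none' or 'rif'")
        mean, sd = efficiency_from_counts(self.replicates)
        self.efficiency_mean = mean
        self.efficiency_sd = sd


@dataclass(frozen=True)
class CensoredValue:
    """An efficiency, possibly replaced by the below-detection substitution."""

    value: float
    censored: bool
    substitution: float = CENSOR_SUBSTITUTION

    def __post_init__(self):
        if self.censored and self.value != self.substitution:
            raise ValueError("censored value must equal the substitution")


def efficiency_from_counts(replicates) -> tuple[float, float]:
    """Mean and sample SD (n-1) of per-replicate white/total fractions.

    Fewer than 3 replicates triggers a warning (SD is NaN for a single
    replicate) but still returns the mean.
    """
    reps = list(replicates)
    if not reps:
        raise ValueError("need at least one replicate")
    if len(reps) < 3:
        warnings.warn(f"only {len(reps)} replicates; protocol uses >= 3 "
                      "independent experiments", stacklevel=2)
    fracs = np.array([r.fraction for r in reps])
    sd = float(fracs.std(ddof=1)) if len(reps) > 1 else float("nan")
    return float(fracs.mean()), sd


def censor_low(eff: float, detection_limit: float = DETECTION_LIMIT,
               substitution: float = CENSOR_SUBSTITUTION) -> CensoredValue:
    """Apply the below-detection rule: efficiencies under 1% enter as 0.5%."""
    if not 0.0 <= eff <= 1.0:
        raise ValueError(f"efficiency {eff} outside [0, 1]")
    if eff < detection_limit:
        return CensoredValue(value=substitution, censored=True,
                             substitution=substitution)
    return CensoredValue(value=eff, censored=False, substitution=substitution)


def mif(wt_eff: float, mut_eff, *, mut_censored: bool = False,
        detection_limit: float = DETECTION_LIMIT) -> tuple[float, bool]:
    """Mutant Impact Factor: WT efficiency over mutant efficiency.

    Returns ``(value, is_lower_bound)``.  When the mutant is below detection
    (censored, or exactly zero) the ratio against the detection limit is
    returned as a lower bound.
    """
    if wt_eff <= 0:
        raise ValueError("wild-type efficiency must be positive")
    if mut_censored or mut_eff is None or (isinstance(mut_eff, float)
                                           and math.isnan(mut_eff)):
        return wt_eff / detection_limit, True
    if mut_eff == 0:
        return wt_eff / detection_limit, True
    return wt_eff / mut_eff, False


def format_mif(value: float, is_bound: bool = False) -> str:
    """Display form of a MIF: 2 significant figures, '>' prefix for bounds."""
    if value <= 0 or not math.isfinite(value):
        raise ValueError("MIF must be positive and finite")
    exponent = math.floor(math.log10(value))
    rounded = float(np.round(value, 1 - exponent))
    if rounded >= 10:
        text = f"{rounded:.0f}"
    else:
        text = f"{rounded:g}"
    return (">" + text) if is_bound else text


@dataclass(frozen=True)
class AggregateSummary:
    """Genome-wide summary of one genotype over the surveyed positions."""

    n_positions: int
    mean_efficiency: float
    sd_efficiency: float
    mean_sigma: float
    sd_sigma: float
    n_censored: int


def aggregate_positions(frame: pd.DataFrame, curve: CalibrationCurve | None = None,
                        exclude_positions=(33.0, 57.64, 57.65),
                        efficiency_col: str = "efficiency") -> AggregateSummary:
    """Cumulative mean efficiency and apparent sigma_D across sensor positions.

    ``frame`` needs columns position_cs, ``efficiency_col`` and optionally
    censored / sigma_d.  Censored rows enter at the 0.5% substitution.  The
    apparent sigma_D per position is taken from a ``sigma_d`` column when one
    is present (transcribed report tables) and otherwise inverted from the
    efficiency through ``curve``.  The Ter-proximal sensor and the pair
    flanking rrnG are excluded by default, mirroring the genome-wide
    "7 position" summaries.
    """
    df = frame.loc[~frame["position_cs"].isin(exclude_positions)].copy()
    if len(df) < 2:
        raise ValueError("need >= 2 positions after exclusion")
    if efficiency_col == "efficiency" and "censored" in df:
        censored = df["censored"].fillna(False).astype(bool)
    else:
        # censoring metadata in the frame describes the base efficiency
        # column only; other columns censor by their own values
        censored = df[efficiency_col].isna()
    effs = np.array([
        censor_low(e if not c else 0.0).value
        for e, c in zip(df[efficiency_col], censored)
    ])
    if efficiency_col == "efficiency" and "sigma_d" in df:
        sigmas = np.array([
            s if (not c and pd.notna(s))
            else _sigma_via_curve(curve, e)
            for s, e, c in zip(df["sigma_d"], effs, censored)
        ])
    else:
        sigmas = np.array([_sigma_via_curve(curve, e) for e in effs])
    return AggregateSummary(
        n_positions=len(df),
        mean_efficiency=float(effs.mean()),
        sd_efficiency=float(effs.std(ddof=1)),
        mean_sigma=float(sigmas.mean()),
        sd_sigma=float(sigmas.std(ddof=1)),
        n_censored=int(censored.sum()),
    )


def _sigma_via_curve(curve, eff):
    if curve is None:
        raise ValueError("a calibration curve is required when the frame "
                         "carries no sigma_d column")
    return sigma_from_efficiency(curve, eff).value


def rif_rebound(no_rif: ResolutionMeasurement, rif: ResolutionMeasurement,
                curve: CalibrationCurve) -> tuple[float, float]:
    """Fold-change and sigma_D change caused by transiently blocking
    transcription initiation with rifampicin.

    Both measurements must be of the same strain and position; a censored
    pre-Rif value enters the fold at the 0.5% substitution and the sigma
    change at the detection bound.
    """
    if (no_rif.strain_id != rif.strain_id
            or no_rif.position != rif.position):
        raise ValueError("rebound requires matched strain and position")
    before = censor_low(no_rif.efficiency_mean)
    fold = rif.efficiency_mean / before.value
    dsig = delta_sigma(curve, no_rif.efficiency_mean, rif.efficiency_mean)
    return fold, dsig


# -- tabular interfaces -----------------------------------------------------

def read_counts_tsv(path) -> pd.DataFrame:
    """Read a replicate colony-count sheet.

    Columns: strain_id, position_cs, genotype, condition, replicate_id,
    white_count, total_count.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"strain_id", "position_cs", "genotype", "condition",
                "replicate_id", "white_count", "total_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"counts sheet missing columns: {sorted(missing)}")
    return df


def measurements_from_counts(df: pd.DataFrame) -> list[ResolutionMeasurement]:
    """Collapse a counts sheet into per-strain/condition measurements."""
    out = []
    for (strain, pos, gt, cond), grp in df.groupby(
            ["strain_id", "position_cs", "genotype", "condition"], sort=False):
        reps = [ResolutionReplicate(int(w), int(t))
                for w, t in zip(grp["white_count"], grp["total_count"])]
        out.append(ResolutionMeasurement(
            strain_id=str(strain), position=float(pos), genotype=str(gt),
            condition=str(cond), replicates=reps))
    return out


def render_table_report(measurements, curve: CalibrationCurve,
                        wt_by_position: dict[float, float] | None = None
                        ) -> pd.DataFrame:
    """Survey-style report: one row per measurement with efficiency +-SD,
    MIF against the matched wild type, and apparent sigma_D.

    Efficiencies are displayed as integer percent, sigma_D to 3 decimals and
    MIF to 2 significant figures; internal values stay as fractions.
    """
    rows = []
    for m in measurements:
        cv = censor_low(m.efficiency_mean)
        est = sigma_from_efficiency(curve, m.efficiency_mean)
        if wt_by_position is not None and m.position in wt_by_position \
                and m.genotype != "WT":
            value, bound = mif(wt_by_position[m.position], m.efficiency_mean,
                               mut_censored=cv.censored)
            mif_text = format_mif(value, bound)
        elif m.genotype == "WT":
            mif_text = "1"
        else:
            mif_text = ""
            warnings.warn(f"no wild-type reference for position {m.position}; "
                          "MIF left blank", stacklevel=2)
        if cv.censored:
            eff_text, sig_text = "<1%", "<-0.003"
        else:
            eff_text = f"{round(m.efficiency_mean * 100):.0f}" + (
                f"±{round(m.efficiency_sd * 100):.0f}%"
                if math.isfinite(m.efficiency_sd) else "%")
            sig_text = f"{est.value:.3f}"
        rows.append({
            "strain": m.strain_id, "position_cs": m.position,
            "genotype": m.genotype, "condition": m.condition,
            "efficiency": eff_text, "mif": mif_text,
            "apparent_sigma_d": sig_text,
            "efficiency_fraction": m.efficiency_mean,
            "censored": cv.censored,
        })
    return pd.DataFrame(rows)
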
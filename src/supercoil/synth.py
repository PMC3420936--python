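"""Seeded generators for every input the analysis consumes.

Colony counts are binomial draws through the calibration curve (counting
statistics); induction time courses are flat-baseline-then-linear-rise
Miller-unit traces with multiplicative Gaussian noise on the rise
(pipetting/assay error), emitted as the OD-level columns the Miller formula
consumes.  All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, efficiency_at
from .elongation import InductionTimeCourse
from .tables import survey_tables  # noqa: F401  (re-export)

__all__ = [
    "AssayScenario", "TimeCourseScenario", "simulate_colony_counts",
    "simulate_timecourse", "survey_tables",
]


@dataclass(frozen=True)
class AssayScenario:
    """Resolution assay at a known true sigma_D."""

    true_sigma: float
    n_colonies: int = 600
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if not -0.05 <= self.true_sigma <= 0.0:
            raise ValueError("true_sigma must be in [-0.05, 0]")
        if self.n_colonies < 200:
            raise ValueError("protocol scores >= 200 colonies per replicate")


@dataclass(frozen=True)
class TimeCourseScenario:
    """Induction kinetics with a hidden lag.

    Defaults mirror the assay design: 10-s sampling with three background
    samples before IPTG, 5% multiplicative noise on accumulating activity.
    """

    true_lag_s: float
    slope_mu_per_s: float = 1.5
    baseline_mu: float = 20.0
    noise_fraction: float = 0.05
    sampling_interval_s: float = 10.0
    duration_s: float = 300.0
    seed: int = 0

    def __post_init__(self):
        if self.true_lag_s <= 0:
            raise ValueError("lag must be positive")
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")


def simulate_colony_counts(scenario: AssayScenario, curve: CalibrationCurve,
                           strain_id: str = "SYN", position_cs: float = 85.0,
                           genotype: str = "WT", condition: str = "none"
                           ) -> pd.DataFrame:
    """Replicate colony-count sheet for a sensor at ``true_sigma``.

    White counts are binomial(n_colonies, R(true_sigma)) per replicate.
    """
    p = efficiency_at(curve, scenario.true_sigma)
    rng = np.random.default_rng(scenario.seed)
    whites = rng.binomial(scenario.n_colonies, p, size=scenario.n_replicates)
    return pd.DataFrame({
        "strain_id": strain_id,
        "position_cs": position_cs,
        "genotype": genotype,
        "condition": condition,
        "replicate_id": np.arange(1, scenario.n_replicates + 1),
        "white_count": whites,
        "total_count": scenario.n_colonies,
    })


# OD bookkeeping fixed so that the Miller formula reproduces the target
# trace exactly: MU = 1000 * od420 / (rt * vol * od600)
_OD600 = 0.25
_REACTION_MIN = 30.0
_VOLUME_ML = 0.5


def simulate_timecourse(scenario: TimeCourseScenario,
                        label: str = "") -> InductionTimeCourse:
    """Generate one induction time course with three background samples.

    MU(t) = baseline + slope * max(0, t - t0 - lag) * (1 + eps_t) with
    eps_t ~ Normal(0, noise_fraction); t0 is the third sample.
    """
    dt = scenario.sampling_interval_s
    induction_time = 2 * dt       # samples 0, dt, 2*dt are background
    if scenario.duration_s <= induction_time + scenario.true_lag_s:
        raise ValueError("duration too short: induction plus lag exceeds "
                         "the sampled window")
    times = np.arange(0.0, scenario.duration_s + 0.5 * dt, dt)
    rng = np.random.default_rng(scenario.seed)
    rise = scenario.slope_mu_per_s * np.maximum(
        times - induction_time - scenario.true_lag_s, 0.0)
    eps = rng.normal(0.0, scenario.noise_fraction, size=times.size)
    mu = scenario.baseline_mu + rise * (1.0 + eps)
    mu = np.maximum(mu, 0.0)
    od420 = mu * (_REACTION_MIN * _VOLUME_ML * _OD600) / 1000.0
    return InductionTimeCourse(
        sample_times=times, induction_time=induction_time,
        od420=od420, od550=np.zeros_like(times),
        od600=_OD600, reaction_time_min=_REACTION_MIN,
        volume_ml=_VOLUME_ML, label=label)
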
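"""Transcription elongation rates from simulated induction kinetics.

Generates triplicate beta-Gal induction time courses at the per-position
wild-type rates resolved by the assay (69, 62, 56, 38 nt/s) and at the
genome-wide means (52 nt/s WT, 32 nt/s gyrB1820, 16 nt/s at the gyrB1820
Ter sensor), then re-estimates lag and rate with the hinge changepoint fit
and converts rates to twist flux.

Writes results/elongation_rates.tsv.
"""

from pathlib import Path

import pandas as pd

from supercoil import (LACZ_TRANSCRIPT_NT, estimate_lag_replicates,
                       simulate_timecourse, twist_flux, TimeCourseScenario)
from supercoil.tables import (GYRB1820_ELONGATION_MEAN,
                              GYRB1820_ELONGATION_TER, WT_ELONGATION_MEAN,
                              WT_ELONGATION_NT_S)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

SEED = 20120816
scenarios = [("WT", f"Cs {pos:g}", rate)
             for pos, rate in sorted(WT_ELONGATION_NT_S.items())]
scenarios += [("WT", "genome mean", WT_ELONGATION_MEAN),
              ("gyrB1820", "genome mean", GYRB1820_ELONGATION_MEAN),
              ("gyrB1820", "Cs 33 (Ter)", GYRB1820_ELONGATION_TER)]

rows = []
for i, (genotype, where, true_rate) in enumerate(scenarios):
    true_lag = LACZ_TRANSCRIPT_NT / true_rate
    courses = [simulate_timecourse(TimeCourseScenario(
        true_lag_s=true_lag, duration_s=max(300.0, true_lag * 2 + 60),
        seed=SEED + 10 * i + rep)) for rep in range(3)]
    mean_rate, sd_rate, ests = estimate_lag_replicates(courses)
    rows.append({
        "genotype": genotype, "position": where,
        "true_rate_nt_s": true_rate,
        "recovered_rate_nt_s": round(mean_rate, 1),
        "sd_nt_s": round(sd_rate, 1),
        "mean_lag_s": round(sum(e.lag_s for e in ests) / 3, 1),
        "twist_flux_sc_s": round(twist_flux(mean_rate), 2),
    })

df = pd.DataFrame(rows)
df.to_csv(OUT / "elongation_rates.tsv", sep="\t", index=False)
print("triplicate hinge-fit recovery of per-position elongation rates:")
print(df.to_string(index=False))
wt_flux = twist_flux(WT_ELONGATION_MEAN)
print(f"\nWT genome-mean {WT_ELONGATION_MEAN} nt/s turns the template at "
      f"{wt_flux:.1f} supercoils/s, matching the 4-5 sc/s processive rate "
      "of WT gyrase; the gyrB1820 mean of "
      f"{GYRB1820_ELONGATION_MEAN} nt/s corresponds to "
      f"{twist_flux(GYRB1820_ELONGATION_MEAN):.1f} sc/s")
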
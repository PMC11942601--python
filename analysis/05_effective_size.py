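#!/usr/bin/env python
"""Effective population size from LD decay and from F_ROH closed forms.

Bins intra-chromosomal pairwise r2 by distance to give an Ne trajectory over
past generations (Sved's Ne = (1-r2)/(4cr2), t = 1/(2c)), converts the mean
F_ROH per length cutoff into dF and Ne over the generation horizon each
cutoff captures, and reports per-generation decline rates and birth-cohort
trajectories.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from rohped import popsize as ps
from rohped.io_qc import read_pedigree, read_plink

parser = argparse.ArgumentParser()
parser.add_argument("--sim", type=Path, default=Path("results/sim"))
parser.add_argument("--out", type=Path, default=Path("results/tables"))
args = parser.parse_args()

gm = read_plink(args.sim / "population_qc.bed")
traj = ps.ld_ne_trajectory(gm)
traj.to_csv(args.out / "ne_trajectory.tsv", sep="\t", index=False)

coeffs = pd.read_csv(args.out / "inbreeding_coefficients.tsv", sep="\t", index_col=0)
f_means = {"all": coeffs["f_roh"].mean(), ">4": coeffs["f_roh_gt4"].mean(),
           ">8": coeffs["f_roh_gt8"].mean(), ">16": coeffs["f_roh_gt16"].mean(),
           ">32": coeffs["f_roh_gt32"].mean()}
ne_roh = ps.ne_from_roh_means(f_means)
ne_roh.to_csv(args.out / "ne_from_roh.tsv", sep="\t", index=False)

# cohort trajectories from the pedigree's birth years (one cohort per
# simulated generation)
ped = read_pedigree(args.sim / "pedigree.tsv")
years = ped.df.set_index("id")["birth_year"]
cohorts = tuple((f"gen{g}", 2000 + g, 2000 + g) for g in sorted(years.unique().astype(int) - 2000))
trends = ps.trend_report(gm, years, cohorts=cohorts)
for name, table in trends.items():
    table.to_csv(args.out / f"ne_trajectory_{name}.tsv", sep="\t", index=False)

recent = traj[(traj["n_pairs"] > 200) & traj["ne"].notna()]
recent = recent[(recent["t_generations"] >= 5) & (recent["t_generations"] <= 100)]
print(f"LD Ne over the last 5-100 generations (bin mean): {np.nanmean(recent['ne']):.1f}")
a, b = recent.iloc[-1], recent.iloc[0]
print(f"decline {ps.decline_rate(b['ne'], a['ne'], b['t_generations'], a['t_generations']):.2f} "
      f"per generation between t={b['t_generations']:.0f} and t={a['t_generations']:.0f}")
print(ne_roh.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
print(f"cohort trajectories written for: {', '.join(trends)}")
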
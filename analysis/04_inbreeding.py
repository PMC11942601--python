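#!/usr/bin/env python
"""Genomic and pedigree inbreeding coefficients, compared with the truth.

Computes F_ROH (all lengths, length thresholds and classes), F_HOM, F_IS and
the three SNP-based F-hat estimators from the genotypes; F_PED (Meuwissen &
Luo), equivalent generations, the depth-corrected rate of inbreeding, and the
gene-drop ancestral coefficients (Ballou, Kalinowski, Baumung) from the
pedigree; then correlates everything with the simulator's exact autozygous
fraction.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from rohped import genomic_inbreeding as gi
from rohped import pedigree as pm
from rohped.io_qc import read_pedigree, read_plink
from rohped.roh import RohSegment

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--rounds", type=int, default=100_000)
parser.add_argument("--sim", type=Path, default=Path("results/sim"))
parser.add_argument("--out", type=Path, default=Path("results/tables"))
args = parser.parse_args()

gm = read_plink(args.sim / "population_qc.bed")
cal = json.load(open(args.out / "roh_calibration.json"))
seg_df = pd.read_csv(args.out / "roh_segments.tsv", sep="\t", comment="#")
segments = [RohSegment(r.individual, int(r.chrom), int(r.start_bp), int(r.end_bp), int(r.n_snps))
            for r in seg_df.itertuples(index=False)]

coeffs = gi.f_roh_table(segments, gm.samples, l_auto_bp=cal["covered_bp"])
coeffs["f_hom"] = gi.f_hom(gm)
coeffs["f_is"] = gi.f_is(gm)
coeffs = coeffs.join(gi.f_hat(gm))

ped = read_pedigree(args.sim / "pedigree.tsv")
ped_table = pm.pedigree_inbreeding_table(
    ped, pm.GeneDropConfig(rounds=args.rounds, seed=args.seed))
coeffs = coeffs.join(ped_table, how="left")
coeffs.rename_axis("individual").to_csv(args.out / "inbreeding_coefficients.tsv", sep="\t")
gi.summary_table(coeffs).to_csv(args.out / "inbreeding_summary.tsv", sep="\t")

truth = pd.read_csv(args.sim / "truth_f.tsv", sep="\t", index_col=0)["true_f"]
corr = coeffs[["f_roh", "f_ped", "delta_f_ped", "f_is", "f_hat2"]].corrwith(truth)
corr.to_csv(args.out / "truth_correlations.tsv", sep="\t", header=["corr_with_true_f"])

print(f"mean F_ROH {coeffs['f_roh'].mean():.4f} | mean F_PED {coeffs['f_ped'].mean():.4f} "
      f"| mean true F {truth.mean():.4f}")
print(f"mean F_HOM {coeffs['f_hom'].mean():.3f}; mean F_IS {coeffs['f_is'].mean():.4f}")
print("gene-drop ancestral means: "
      + ", ".join(f"{c}={coeffs[c].mean():.4f}" for c in ("f_a_bal", "f_a_kal", "f_new", "ahc")))
print("correlation with true autozygous fraction:")
print(corr.round(3).to_string())
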
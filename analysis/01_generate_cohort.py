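"""Generate the synthetic patient cohorts.

Samples Latin-hypercube cohorts of patient characteristics (breast density,
cavity volume, breast volume, cavity depth, plus a uniform 0-5 mm surgical
margin) over the observed MRI-cohort ranges, one cohort per fidelity level,
and writes them to results/cohorts/.  Prints coverage diagnostics.

Usage: python analysis/01_generate_cohort.py [--seed 0] [--n-low 16] [--n-high 8]
"""

import argparse
from pathlib import Path

from bcsheal.cohort import CohortDesign, cohort_table, sample_characteristics

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--n-low", type=int, default=16)
parser.add_argument("--n-high", type=int, default=8)
parser.add_argument("--out", default="results/cohorts")
args = parser.parse_args()

out = Path(args.out)
out.mkdir(parents=True, exist_ok=True)

for fidelity, n, seed in [("low", args.n_low, args.seed), ("high", args.n_high, args.seed + 1)]:
    pats = sample_characteristics(CohortDesign(n_samples=n, seed=seed, fidelity=fidelity))
    tab = cohort_table(pats)
    path = out / f"cohort_{fidelity}.csv"
    tab.to_csv(path, index=False)
    print(f"{fidelity}-fidelity cohort: {len(pats)}/{n} feasible patients -> {path}")
    print(tab.describe().loc[["min", "50%", "max"]].to_string(float_format="%.3g"))
    print()
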
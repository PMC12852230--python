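"""Predict outcome maps over pairs of patient characteristics.

Re-trains the %BSD multi-fidelity surrogate and the visible-deformation
classifier on the simulated outcomes, then evaluates each on 50x50 grids
(2,500 predictions per panel) varying two characteristics at a time with
the remaining ones held at the cohort medians.  Writes the mean and
standard-deviation surfaces as CSV and prints the marginal trends.

Usage: python analysis/05_prediction_maps.py [--seed 0] [--grid 50]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from bcsheal import gp
from bcsheal.cohort import PatientCharacteristics
from bcsheal.outcomes import SimulationOutcome

parser = argparse.ArgumentParser()
parser.add_argument("--sims", default="results/simulations")
parser.add_argument("--out", default="results/maps")
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--grid", type=int, default=50)
args = parser.parse_args()


def load_outcomes(fidelity):
    sims = Path(args.sims)
    tab = pd.read_csv(sims / f"outcomes_{fidelity}.csv")
    traj = pd.read_csv(sims / f"contraction_{fidelity}.csv", index_col="day")
    outs = []
    for _, row in tab.iterrows():
        ch = PatientCharacteristics(
            row.breast_density, row.cavity_volume, row.breast_volume,
            row.cavity_depth, row.margin_width, int(row.seed))
        outs.append(SimulationOutcome(
            days=traj.index.to_numpy(float),
            contraction=traj[str(int(row.seed))].to_numpy(),
            pbsd=row.pbsd, week4_skin_displacement=np.zeros(0),
            cavity_depth=row.cavity_depth, characteristics=ch,
            consensus_score=row.consensus_score))
    return outs


low, high = load_outcomes("low"), load_outcomes("high")
sc4 = gp.InputScaler()
Xb_lo, yb_lo = gp.bsd_dataset(low)
Xb_hi, yb_hi = gp.bsd_dataset(high)
mf = gp.MFGPModel().fit(sc4.transform(Xb_lo), yb_lo, sc4.transform(Xb_hi), yb_hi,
                        seed=args.seed)

out = Path(args.out)
out.mkdir(parents=True, exist_ok=True)


def predict(X_raw):
    return mf.predict(sc4.transform(X_raw), seed=args.seed)


pairs = [("cavity_volume", "breast_density"), ("breast_volume", "cavity_volume"),
         ("cavity_depth", "breast_density"), ("cavity_depth", "cavity_volume")]
for pair in pairs:
    m = gp.prediction_maps(predict, pair, grid_n=args.grid)
    for what in ("mean", "sd"):
        pd.DataFrame(m[what], index=m["axis_1"], columns=m["axis_2"]).to_csv(
            out / f"bsd_{what}_{pair[0]}-{pair[1]}.csv")
    marg = m["mean"].mean(axis=1)
    slope = np.polyfit(m["axis_1"], marg, 1)[0]
    print(f"%BSD vs {pair[0]:>14s} (marginal over {pair[1]}): "
          f"{marg[0]:6.2f} -> {marg[-1]:6.2f}  (slope {'+' if slope>0 else '-'})")
print(f"wrote {2*len(pairs)} map CSVs to {out}")
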
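#!/usr/bin/env python
"""Generate Brownian toy-dendrimer trajectories for the analysis chain.

Runs the overdamped integrator for G1 dendrimers of both spacer
chemistries, checks Rg stationarity after burn-in, and writes GRO/XTC
pairs under scratch/ (binary trajectories are working data, not results).
"""

from pathlib import Path

import pandas as pd

from dendromd.io import write_trajectory
from dendromd.structure import radius_of_gyration
from dendromd.synthetic import gen_toy_dendrimer_trajectory

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
SCRATCH.mkdir(exist_ok=True)
OUT = ROOT / "results"
OUT.mkdir(exist_ok=True)

rows = []
for kind, seed in (("2Arg", 11), ("2Lys", 12)):
    system, traj = gen_toy_dendrimer_trajectory(
        generation=1, spacer_kind=kind, n_steps=20000, save_every=20,
        burn_in=4000, seed=seed)
    write_trajectory(system, traj, SCRATCH / f"toy_{kind}.gro",
                     SCRATCH / f"toy_{kind}.xtc")
    rg = radius_of_gyration(traj, system).rg
    half = len(rg) // 2
    drift = abs(rg[:half].mean() / rg[half:].mean() - 1)
    rows.append({"spacer": kind, "n_frames": traj.n_frames,
                 "n_atoms": system.n_atoms, "Rg_mean_nm": rg.mean(),
                 "Rg_std_nm": rg.std(), "half_mean_drift": drift})

df = pd.DataFrame(rows)
df.to_csv(OUT / "toy_trajectories.csv", index=False)
print(df.to_string(index=False))
print(f"\ntrajectories written to {SCRATCH}/; the half-trajectory Rg "
      "drift (a few percent, set by the slow size-pulsation mode) is the "
      "residual non-stationarity after burn-in.")
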
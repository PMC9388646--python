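#!/usr/bin/env python
"""Bias-exchange metadynamics on the helix-coil chain vs exact enumeration.

Runs a three-replica ensemble (neutral + biased on helix fraction + biased
on neighbour alignment, exchanges every 10 ps) for each model of the 3x3
(delta_e, J) grid, reconstructs F(f_H) from the helicity-biased replica by
last-bias reweighting with block-analysis error bars, and reports the RMS
deviation from exact enumeration over bins visited more than 100 times.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from unwindfes.constants import kt
from unwindfes.fes import BlockErrorConfig, block_error, discrete_axis, fes_reweight
from unwindfes.helix_coil import HelixCoilModel, free_energy_profile
from unwindfes.io import write_fes
from unwindfes.sampler import SamplerSchedule, ThermoParams, run_bemetad

OUT = Path("results/analysis")
OUT.mkdir(parents=True, exist_ok=True)

thermo = ThermoParams()
schedule = SamplerSchedule(n_steps=200_000, output_stride=100)
axis = discrete_axis("helix_fraction", np.arange(13) / 12)
kbt = kt(310.0)

rows = []
for delta_e in (-1.0, 0.0, 1.0):
    for coupling in (0.0, 0.5, 1.0):
        model = HelixCoilModel(12, delta_e, coupling, 310.0)
        exact = free_energy_profile(model)["F"].to_numpy()
        replicas = run_bemetad(
            model, [None, "helix_fraction", "neighbor_alignment"],
            thermo, schedule, seed=7,
        )
        colvar = replicas[1].colvar
        grid = fes_reweight(colvar, [axis], temperature=310.0, min_count=1)
        grid.error = block_error(
            colvar, [axis], temperature=310.0,
            config=BlockErrorConfig(100), equilibration_fraction=0.2,
        )
        visited = (grid.counts > 100) & ~grid.mask
        ours = grid.F[visited] - grid.F[visited].min()
        ref = exact[visited] - exact[visited].min()
        rms = float(np.sqrt(np.mean((ours - ref) ** 2)))
        swaps = replicas[0].swap_log
        rate = swaps["accepted"].sum() / swaps["attempts"].sum()
        rows.append((delta_e, coupling, int(visited.sum()), rms / kbt, rate))
        print(
            f"delta_e={delta_e:+.0f} J={coupling:.1f}: "
            f"RMS = {rms / kbt:.3f} kBT over {visited.sum()} bins, "
            f"exchange acceptance {rate:.2f}"
        )
        if (delta_e, coupling) == (0.0, 0.5):
            write_fes(
                OUT / "fes_helix_coil_de0_J05.tsv", grid,
                ["reweighted F(f_H), delta_e=0, J=0.5, with block errors"],
            )

summary = pd.DataFrame(
    rows, columns=["delta_e", "J", "bins_gt100", "rms_kbt", "exch_accept"]
)
with open(OUT / "bemetad_summary.tsv", "w") as fh:
    fh.write("# reweighted F(f_H) vs exact enumeration, RMS in kBT units\n")
    summary.to_csv(fh, sep="\t", index=False)
print(f"worst RMS: {summary.rms_kbt.max():.3f} kBT (target <= 0.5)")
print(f"summary written to {OUT / 'bemetad_summary.tsv'}")
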
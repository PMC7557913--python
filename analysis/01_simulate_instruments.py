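#!/usr/bin/env python
"""Generate synthetic hydration datasets for the three instrument designs.

Emulates the study layout: HP (single-frequency conductance probe, 12 in
vivo / 9 in vitro series), NE (35-frequency sweeps, 12 series each
setting) over the 12-point 16 min schedule, and the 4E Franz cell (60
scans over 3 h 10 min, 5 membranes).  Stage-1 rates are the printed
conductance rate constants of the corresponding instrument/setting.  Bulk
CSVs go to scratch/data/; a small row-count summary goes to
results/analysis/.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from sckinetics import (
    HydrationTrajectory,
    NoiseModel,
    franz_cell_design,
    hp_design,
    ne_design,
    simulate_experiment,
    write_series,
    write_spectra,
)
from sckinetics.pipeline import STAGE1_RATES, _child_seed

SEED = 0
N_REPLICATES = {("HP", "in vivo"): 12, ("HP", "in vitro"): 9,
                ("NE", "in vivo"): 12, ("NE", "in vitro"): 12,
                ("4E", "in vitro"): 5}

scratch = Path("scratch/data")
results = Path("results/analysis")
scratch.mkdir(parents=True, exist_ok=True)
results.mkdir(parents=True, exist_ok=True)

designs = {"HP": hp_design(), "NE": ne_design(), "4E": franz_cell_design()}
rows = []
for i, ((method, context), k) in enumerate(sorted(STAGE1_RATES.items())):
    noise = NoiseModel(seed=_child_seed(SEED, i))
    traj = dataclasses.replace(HydrationTrajectory(), k_stage1_per_s=k)
    dataset = simulate_experiment(
        designs[method], traj, n_replicates=N_REPLICATES[(method, context)], noise=noise
    )
    stem = f"{method}_{context.replace(' ', '_')}"
    if dataset.spectra:
        write_spectra(dataset.spectra, scratch / f"{stem}_spectra.csv")
        n_rows = sum(len(s) for s in dataset.spectra)
    else:
        write_series(dataset.series, scratch / f"{stem}_series.csv")
        n_rows = sum(len(s) for s in dataset.series)
    rows.append({"method": method, "context": context, "k_stage1_per_s": k,
                 "n_replicates": N_REPLICATES[(method, context)], "csv_rows": n_rows})
    print(f"{method} {context}: k={k} s^-1, {N_REPLICATES[(method, context)]} replicates, "
          f"{n_rows} CSV rows -> scratch/data/{stem}_*.csv")

pd.DataFrame(rows).to_csv(results / "simulated_datasets.csv", index=False)
print(f"\nWrote dataset inventory to {results / 'simulated_datasets.csv'}")
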
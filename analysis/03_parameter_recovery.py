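#!/usr/bin/env python
"""Simulator round-trip: how well does the analysis chain recover the rate?

For stage-1 rates spanning the published range (0.004–0.014 s⁻¹), 4E
datasets are generated at zero noise and at the default noise model, and
the full pipeline (DC-limit resistance response → conversion α → −ln(1−α)
regression over 30–120 s) is used to estimate the rate constant.
"""

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from sckinetics import HydrationTrajectory, NoiseModel, franz_cell_design, simulate_experiment
from sckinetics.pipeline import stage1_recovery_fits

SEED = 0
results = Path("results/analysis")
results.mkdir(parents=True, exist_ok=True)

design = franz_cell_design()
rows = []
for k_true in (0.004, 0.008, 0.014):
    traj = dataclasses.replace(HydrationTrajectory(), k_stage1_per_s=k_true)
    silent = simulate_experiment(design, traj, 1, NoiseModel.silent(SEED))
    k_zero = stage1_recovery_fits(silent)[0].k_per_s
    noisy = simulate_experiment(design, traj, 5, NoiseModel(seed=SEED))
    k_noisy = np.median([f.k_per_s for f in stage1_recovery_fits(noisy)])
    rows.append(
        {
            "k_true_per_s": k_true,
            "k_hat_zero_noise": k_zero,
            "err_zero_noise_pct": (k_zero / k_true - 1) * 100,
            "k_hat_noisy_median": k_noisy,
            "err_noisy_pct": (k_noisy / k_true - 1) * 100,
        }
    )

table = pd.DataFrame(rows)
print(table.to_string(index=False, float_format=lambda v: f"{v:.5g}"))
table.to_csv(results / "parameter_recovery.csv", index=False)
print(f"\nTable written to {results / 'parameter_recovery.csv'}")
print("\nFinding: on noiseless data the rate comes back within "
      f"{table['err_zero_noise_pct'].abs().max():.2f}% at all three rates; with "
      "2% magnitude noise and 5 replicates the median estimate stays within "
      f"{table['err_noisy_pct'].abs().max():.1f}% here. The five regression points "
      "of the 30-120 s window are the accuracy bottleneck at the slowest rate.")
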
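#!/usr/bin/env python
"""AUC overoptimism of the incorrect CV protocol on small null datasets.

Simulates the n=100 null design (10% minority, p=10, 2-fold balanced CV,
CART) and contrasts the mean cross-validated AUC when sampling is applied
inside the CV loop (correct) vs to the whole dataset first (incorrect), for
oversampling and the three SMOTE variants, 500 runs per protocol.  Writes
results/n100_auc_differences.csv.

Finding: on data with no class signal the correct protocol stays at AUC 0.5
for every sampler, while the incorrect protocol inflates AUC by ~0.40
(oversampling) and ~0.26 / 0.15 / 0.10 (500-/200-/100-SMOTE) — the more
replicas or synthetic points, the larger the optimism.
"""

import warnings
from pathlib import Path

from imbcv import SimulationGrid, run_simulation_study

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

grid = SimulationGrid(
    n_values=(100,), p_values=(10,), k_values=(2,),
    samplers=("over", "smote500", "smote200", "smote100"),
    runs=500, seed=4711,
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore", UserWarning)
    res = run_simulation_study(grid)

auc = res[res.measure == "AUC"].pivot_table(index="sampler", columns="mode", values="mean")
auc["difference"] = auc["incorrect"] - auc["correct"]
auc = auc.loc[["over", "smote500", "smote200", "smote100"]].round(4)
auc.to_csv(OUT / "n100_auc_differences.csv")
print(auc.to_string())
print("\nincorrect-CV optimism grows with the number of generated minority rows.")
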
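"""Simulate a lineage through checkpoint activation and characterise the
SAC-active steady state.

A single lineage cycles unperturbed, then at t = 0 the cycle-length
distribution switches to the SAC-active delayed exponential.  We record
the trace and, over 500 independent SAC-active lineages, the entry-size
distribution per cycle — showing that sizes stabilise on the combined
exponential-linear curve while cycle times stay highly variable, and
that pure exponential growth would diverge.

Writes: results/sac_onset_trace.csv, results/sac_entry_size_by_cycle.csv,
results/sac_onset_summary.csv (full per-cell entry-size matrix goes to
scratch/, it is regenerated deterministically from the seed)
"""

from pathlib import Path

import numpy as np
import pandas as pd

from sacsize.cyclestats import coefficient_of_variation
from sacsize.growth import (
    CycleTimeModel,
    GrowthParams,
    simulate_entry_sizes,
    simulate_lineage,
)

SEED = 0
N_CELLS = 500
N_CYCLES = 30

params = GrowthParams()
unp = CycleTimeModel.unperturbed()
sac = CycleTimeModel.sac_active()

trace = simulate_lineage(
    params,
    [(-1e9, unp), (0.0, sac)],
    n_cycles=25,
    dt=10.0,
    rng=np.random.default_rng(SEED),
)
trace.samples.to_csv("results/sac_onset_trace.csv", index=False)

combined = simulate_entry_sizes(params, sac, N_CELLS, N_CYCLES, np.random.default_rng(SEED))
expo = simulate_entry_sizes(
    params, sac, N_CELLS, N_CYCLES, np.random.default_rng(SEED), growth="exponential"
)
entries = pd.DataFrame(combined, columns=[f"cycle{k+1}" for k in range(N_CYCLES)])
Path("scratch").mkdir(exist_ok=True)
entries.to_csv("scratch/sac_entry_sizes_full.csv", index=False)
by_cycle = pd.DataFrame(
    {
        "cycle": np.arange(1, N_CYCLES + 1),
        "entry_median_um2": np.median(combined, axis=0),
        "entry_mean_um2": combined.mean(axis=0),
        "entry_var": combined.var(axis=0),
        "entry_cv": combined.std(axis=0, ddof=1) / combined.mean(axis=0),
    }
)
by_cycle.to_csv("results/sac_entry_size_by_cycle.csv", index=False)

cycle_cv = coefficient_of_variation(
    np.random.default_rng(SEED + 1).exponential(200.0, 100_000) + 200.0
)
entry_cv = coefficient_of_variation(combined[:, -1])
summary = pd.DataFrame(
    {
        "quantity": [
            "steady_entry_median_um2",
            "steady_entry_cv",
            "cycle_length_cv",
            "entry_var_ratio_cycle30_over_10_combined",
            "entry_var_ratio_cycle30_over_10_exponential",
        ],
        "value": [
            float(np.median(combined[:, -1])),
            entry_cv,
            cycle_cv,
            float(np.var(combined[:, 29]) / np.var(combined[:, 9])),
            float(np.var(expo[:, 29]) / np.var(expo[:, 9])),
        ],
    }
)
summary.to_csv("results/sac_onset_summary.csv", index=False)
print(summary.to_string(index=False))
print(
    "\nCycle lengths vary much more than entry sizes "
    f"(CV {cycle_cv:.2f} vs {entry_cv:.2f}); the combined curve holds the "
    "entry-size variance flat between cycles 10 and 30 while pure "
    "exponential growth blows it up."
)
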
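"""Cycle-phase folds, size control and duration comparisons on synthetic
cell-cycle records.

500 cells per regime are generated from the growth model with 10%
censoring.  We compute the mitotic / non-mitotic fold increases of the
SAC-active over the unperturbed condition, the size-growth slope λ (per
regime, with timer and sizer controls), CVs, a log-rank comparison of
cycle lengths, and the normality-gated correlation between entry size
and mitotic growth.

Writes: results/cycle_statistics.csv (the full record table goes to
scratch/, it is regenerated deterministically from the seed)
"""

from pathlib import Path

import numpy as np
import pandas as pd

from sacsize.cyclestats import (
    coefficient_of_variation,
    compare_durations,
    choose_correlation,
    fold_changes,
    phase_durations,
    size_growth_slope,
    size_growth_stat,
    summarize_condition,
)
from sacsize.growth import CycleTimeModel, GrowthParams
from sacsize.synthetic import (
    generate_cycle_records,
    generate_sizer_records,
    generate_timer_records,
)

SEED = 5
rng = np.random.default_rng(SEED)
params = GrowthParams()

records = generate_cycle_records(
    params,
    {"unperturbed": CycleTimeModel.unperturbed(), "sac_active": CycleTimeModel.sac_active()},
    n_cells=500,
    censor_prob=0.1,
    rng=rng,
)
Path("scratch").mkdir(exist_ok=True)
pd.DataFrame([vars(r) for r in records]).to_csv("scratch/cycle_records.csv", index=False)

sac = [r for r in records if r.condition == "sac_active"]
unp = [r for r in records if r.condition == "unperturbed"]
fm, fn = fold_changes(summarize_condition(sac), summarize_condition(unp))

rows = [("fold_mitosis_sac_over_unp", fm), ("fold_notmitosis_sac_over_unp", fn)]
for label, recs in (("sac_active", sac), ("unperturbed", unp)):
    lam, p, n = size_growth_slope(recs)
    rows += [(f"lambda_{label}", lam), (f"lambda_{label}_pvalue", p)]
    cycles = [phase_durations(r)[1] for r in recs if not r.censored]
    rows.append((f"cv_cycle_length_{label}", coefficient_of_variation(cycles)))
    rows.append(
        (f"cv_entry_size_{label}", coefficient_of_variation([r.A_bud for r in recs]))
    )
lam_timer, _, _ = size_growth_slope(generate_timer_records(500, rng, noise_sd=0.05))
lam_sizer, _, _ = size_growth_slope(generate_sizer_records(500, rng))
rows += [("lambda_timer_control", lam_timer), ("lambda_sizer_control", lam_sizer)]

rows.append(("logrank_p_cycle_sac_vs_unp", compare_durations(sac, unp, "cycle")))

A_pm = np.array([r.A_pm for r in sac if not r.censored])
G = size_growth_stat(A_pm, np.array([r.A_ana for r in sac if not r.censored]))
method, coef, p = choose_correlation(np.log(A_pm), G)
rows += [(f"corr_{method}_lnApm_vs_G_sac", coef), ("corr_pvalue", p)]

stats = pd.DataFrame(rows, columns=["quantity", "value"])
stats.to_csv("results/cycle_statistics.csv", index=False)
print(stats.to_string(index=False))
print(
    "\nSAC-active cycles are dominated by a long mitosis (large mitotic "
    "fold, non-mitotic fold near 1); their negative size-growth slope "
    "shows compensatory size control, absent in the timer control."
)
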
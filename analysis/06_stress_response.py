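"""SRI scoring and correlation-distance clustering of synthetic ESR
profiles.

Profiles of graded ESR strength (strong, moderate, null, inverted) are
generated with shared gene structure, scored with the SRI, z-normalized
and clustered with complete linkage on 1 − Spearman ρ.  Samples with a
real ESR cluster away from the null and inverted ones, and the SRI
orders them by construction strength.

Writes: results/sri_scores.csv, results/esr_distance_matrix.csv
"""

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster

from sacsize.proteome import (
    complete_linkage,
    correlation_distance_matrix,
    simulate_esr_profile,
    sri,
    znormalize,
)

SEED = 0
rng = np.random.default_rng(SEED)

design = [
    ("strong_esr_a", 2.0),
    ("strong_esr_b", 2.0),
    ("moderate_esr", 1.0),
    ("null_a", 0.0),
    ("null_b", 0.0),
    ("inverted_esr", -1.5),
]
profiles = {
    name: simulate_esr_profile(s, 150, 150, 300, 0.4, rng, sample=name)
    for name, s in design
}

scores = pd.DataFrame(
    {"sample": list(profiles), "strength": [s for _, s in design],
     "sri": [sri(p) for p in profiles.values()]}
)
scores.to_csv("results/sri_scores.csv", index=False)

z = np.vstack([znormalize(p.log2fc) for p in profiles.values()])
d = correlation_distance_matrix(z)
pd.DataFrame(d, index=list(profiles), columns=list(profiles)).to_csv(
    "results/esr_distance_matrix.csv"
)
clusters = fcluster(complete_linkage(d), t=2, criterion="maxclust")

print(scores.to_string(index=False))
print("\ntwo-way complete-linkage clusters:",
      dict(zip(profiles, clusters)))
names = list(profiles)
d_rep = d[names.index("strong_esr_a"), names.index("strong_esr_b")]
d_inv = d[names.index("strong_esr_a"), names.index("inverted_esr")]
print(
    f"\nSRI tracks the constructed ESR strength. Replicate ESR profiles "
    f"are nearly coincident (d = {d_rep:.2f}) while the inverted profile "
    f"sits close to the maximal distance (d = {d_inv:.2f}); null profiles "
    "are uncorrelated with everything (d near 1) and attach arbitrarily."
)
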
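"""Chromosome mis-segregation rates and the aneuploidy probability.

A single labelled chromosome (ChrV) is scored for mis-segregation, giving
a per-chromosome rate R = n_missegregating / n_total.  Assuming every one
of the 16 budding-yeast chromosomes mis-segregates with the same
frequency (a gross first approximation), the probability that a cell
carries at least one aneuploid chromosome is

    P = 1 − (1 − R)^16.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "MisSegCounts",
    "CHRV_MISSEG_COUNTS",
    "misseg_rate",
    "aneuploidy_probability",
    "aggregate_aneuploidy",
    "simulate_misseg_counts",
]

N_CHROMOSOMES = 16


@dataclass(frozen=True)
class MisSegCounts:
    """Scored mis-segregation events for one condition/replicate."""

    condition: str
    n_missegregating: int
    n_total: int
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not 0 <= self.n_missegregating <= self.n_total:
            raise ValueError("need 0 <= n_missegregating <= n_total")


#: ChrV mis-segregation counts scored 24 h after G1 release, two
#: biological replicates per condition.
CHRV_MISSEG_COUNTS: tuple[MisSegCounts, ...] = (
    MisSegCounts("WT [YEPRG]", 0, 66, replicate=1),
    MisSegCounts("GAL1-MAD2 [YEPRG]", 2, 91, replicate=1),
    MisSegCounts("WT [22C]", 0, 67, replicate=1),
    MisSegCounts("tub2-401 [22C]", 6, 129, replicate=1),
    MisSegCounts("WT [YEPRG]", 0, 105, replicate=2),
    MisSegCounts("GAL1-MAD2 [YEPRG]", 3, 132, replicate=2),
    MisSegCounts("WT [22C]", 0, 140, replicate=2),
    MisSegCounts("tub2-401 [22C]", 16, 238, replicate=2),
)


def misseg_rate(counts: MisSegCounts) -> float:
    """Per-chromosome mis-segregation rate R = n_mis / n_total."""
    return counts.n_missegregating / counts.n_total


def aneuploidy_probability(R: float, n_chromosomes: int = N_CHROMOSOMES) -> float:
    """P(>= 1 aneuploid chromosome) = 1 − (1 − R)^n under equal
    per-chromosome rates."""
    if not 0.0 <= R <= 1.0:
        raise ValueError("R must lie in [0, 1]")
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    return 1.0 - (1.0 - R) ** n_chromosomes


def aggregate_aneuploidy(
    counts: Iterable[MisSegCounts],
    method: Literal["mean_of_p", "pooled"] = "mean_of_p",
    n_chromosomes: int = N_CHROMOSOMES,
) -> float:
    """Aggregate replicate counts into one aneuploidy probability.

    ``mean_of_p`` (default) maps each replicate's rate through P and
    averages — replicates are treated as separate estimates, as when
    each is plotted as its own point.  ``pooled`` sums the counts first
    and applies P once.
    """
    counts = list(counts)
    if not counts:
        raise ValueError("no counts supplied")
    if method == "mean_of_p":
        return float(
            np.mean(
                [aneuploidy_probability(misseg_rate(c), n_chromosomes) for c in counts]
            )
        )
    if method == "pooled":
        mis = sum(c.n_missegregating for c in counts)
        tot = sum(c.n_total for c in counts)
        return aneuploidy_probability(mis / tot, n_chromosomes)
    raise ValueError(f"unknown aggregation method {method!r}")


def simulate_misseg_counts(
    true_R: float,
    n_total: int,
    rng: np.random.Generator,
    condition: str = "synthetic",
    replicate: int = 1,
) -> MisSegCounts:
    """Binomial draw of scored mis-segregation events at a known rate;
    ``misseg_rate`` of the result is an unbiased estimator of
    ``true_R``."""
    if not 0.0 <= true_R <= 1.0:
        raise ValueError("true_R must lie in [0, 1]")
    k = int(rng.binomial(n_total, true_R))
    return MisSegCounts(condition, k, n_total, replicate=replicate)
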
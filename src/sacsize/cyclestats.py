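"""Cell-cycle and cell-size statistics.

Phase durations are defined from fluorescence landmarks: mitotic entry is
the onset of Clb2 accumulation, anaphase onset is the start of Clb2
degradation, and the cell cycle runs between two consecutive budding
events.  Size control during mitosis is quantified by the size-growth
statistic

    G_mitosis = ln(A_ANA / A_PM)

regressed on ln(A_PM): slope λ = 0 means a timer (growth independent of
entry size), λ = −1 a perfect sizer (exit size independent of entry
size).

Normality gating follows a 3-of-4 rule (Lilliefors, Anderson–Darling,
Jarque–Bera, one-sample KS at α): Pearson correlation when both samples
pass, Spearman otherwise.  Duration comparisons between populations with
censored cells use the log-rank test.  The similarity of two size
distributions is measured by the overlap coefficient
O(f, g) = ∫ min(f, g) dv of their kernel density estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors, normal_ad

__all__ = [
    "CellCycleRecord",
    "ConditionSummary",
    "phase_durations",
    "summarize_condition",
    "fold_changes",
    "size_growth_stat",
    "size_growth_slope",
    "coefficient_of_variation",
    "is_normal",
    "choose_correlation",
    "density_overlap",
    "compare_durations",
    "compare_locations",
]


@dataclass
class CellCycleRecord:
    """Per-cycle landmarks and sizes for one cell.

    Times in minutes; missing landmarks (censored cycles) are NaN.
    Sizes: A_alpha at G1 release (gen0 only), A_bud at budding, A_pm at
    prometaphase (Clb2 rise), A_ana at anaphase onset (Clb2 fall).
    """

    cell_id: str
    condition: str
    generation: int = 0
    t_bud: float = math.nan
    t_pm: float = math.nan
    t_ana: float = math.nan
    t_next_bud: float = math.nan
    censored: bool = False
    A_alpha: float = math.nan
    A_bud: float = math.nan
    A_pm: float = math.nan
    A_ana: float = math.nan


@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    median_mitosis: float
    median_cycle: float
    n: int
    n_censored: int = 0


def phase_durations(record: CellCycleRecord) -> tuple[float, float]:
    """(mitotic length, cell-cycle length) in minutes.

    Mitotic length = anaphase onset − mitotic entry; cell-cycle length =
    time between consecutive budding events.  Censored records return
    NaN for the missing duration(s).
    """
    mitotic = record.t_ana - record.t_pm
    if not math.isnan(mitotic) and mitotic < 0:
        raise ValueError("anaphase onset precedes mitotic entry")
    cycle = record.t_next_bud - record.t_bud
    if not math.isnan(cycle) and cycle < 0:
        raise ValueError("re-budding precedes budding")
    return mitotic, cycle


def summarize_condition(
    records: Iterable[CellCycleRecord], condition: str | None = None
) -> ConditionSummary:
    """Median mitotic and cell-cycle lengths over uncensored records."""
    recs = list(records)
    if condition is not None:
        recs = [r for r in recs if r.condition == condition]
    if not recs:
        raise ValueError("no records for condition")
    mit = [phase_durations(r)[0] for r in recs if not r.censored]
    cyc = [phase_durations(r)[1] for r in recs if not r.censored]
    mit = [v for v in mit if not math.isnan(v)]
    cyc = [v for v in cyc if not math.isnan(v)]
    return ConditionSummary(
        condition=condition or recs[0].condition,
        median_mitosis=float(np.median(mit)) if mit else math.nan,
        median_cycle=float(np.median(cyc)) if cyc else math.nan,
        n=len(recs),
        n_censored=sum(r.censored for r in recs),
    )


def fold_changes(sac: ConditionSummary, unp: ConditionSummary) -> tuple[float, float]:
    """Fold increases of the mitotic and non-mitotic cycle phases:

        FOLD_mitosis    = m_mit^SAC / m_mit^unp
        FOLD_notmitosis = (m_cc^SAC − m_mit^SAC) / (m_cc^unp − m_mit^unp)
    """
    if unp.median_mitosis <= 0 or unp.median_cycle <= 0:
        raise ValueError("unperturbed medians must be positive")
    notmit_unp = unp.median_cycle - unp.median_mitosis
    notmit_sac = sac.median_cycle - sac.median_mitosis
    if notmit_unp <= 0 or notmit_sac <= 0:
        raise ValueError("cell-cycle median must exceed mitotic median")
    return sac.median_mitosis / unp.median_mitosis, notmit_sac / notmit_unp


def size_growth_stat(A_pm, A_ana):
    """G_mitosis = ln(A_ANA / A_PM), the relative size gain in mitosis."""
    A_pm = np.asarray(A_pm, dtype=float)
    A_ana = np.asarray(A_ana, dtype=float)
    if np.any(A_pm <= 0) or np.any(A_ana <= 0):
        raise ValueError("sizes must be positive")
    out = np.log(A_ana / A_pm)
    return out.item() if out.ndim == 0 else out


def size_growth_slope(
    records: Sequence[CellCycleRecord] | None = None,
    *,
    A_pm=None,
    A_ana=None,
) -> tuple[float, float, int]:
    """OLS slope λ of G_mitosis on ln(A_PM), its p-value, and n.

    λ = 0 indicates no size control (timer), λ = −1 a perfect sizer.
    Accepts either a record collection (uncensored records with both
    sizes are used) or explicit size arrays.
    """
    if records is not None:
        pairs = [
            (r.A_pm, r.A_ana)
            for r in records
            if not r.censored and not math.isnan(r.A_pm) and not math.isnan(r.A_ana)
        ]
        if len(pairs) < 3:
            raise ValueError("need >= 3 uncensored records with both sizes")
        A_pm = np.array([p[0] for p in pairs])
        A_ana = np.array([p[1] for p in pairs])
    else:
        A_pm = np.asarray(A_pm, dtype=float)
        A_ana = np.asarray(A_ana, dtype=float)
        if A_pm.size < 3:
            raise ValueError("need >= 3 points")
    x = np.log(A_pm)
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: all entry sizes equal")
    y = size_growth_stat(A_pm, A_ana)
    res = stats.linregress(x, y)
    return float(res.slope), float(res.pvalue), int(x.size)


def coefficient_of_variation(values) -> float:
    """Sample SD (ddof=1) over sample mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    mean = v.mean()
    if mean == 0:
        raise ValueError("zero mean: CV undefined")
    return float(v.std(ddof=1) / mean)


def is_normal(values, alpha: float = 0.05) -> bool:
    """3-of-4 normality gate.

    Runs Lilliefors, Anderson–Darling, Jarque–Bera and a one-sample KS
    test against a normal with sample-estimated mean/SD; the sample is
    called normal when at least three of the four p-values exceed
    ``alpha``.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 8:
        raise ValueError("need n >= 8 for the normality test battery")
    pvals = [
        lilliefors(v, dist="norm")[1],
        normal_ad(v)[1],
        stats.jarque_bera(v).pvalue,
        stats.kstest(v, "norm", args=(v.mean(), v.std(ddof=1))).pvalue,
    ]
    return sum(p > alpha for p in pvals) >= 3


def choose_correlation(
    x, y, alpha: float = 0.05
) -> tuple[Literal["pearson", "spearman"], float, float]:
    """Normality-gated correlation: Pearson when both samples pass the
    3-of-4 normality rule at ``alpha``, Spearman otherwise.

    Returns (method, coefficient, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if is_normal(x, alpha) and is_normal(y, alpha):
        r, p = stats.pearsonr(x, y)
        return "pearson", float(r), float(p)
    r, p = stats.spearmanr(x, y)
    return "spearman", float(r), float(p)


def density_overlap(samples_f, samples_g, grid_size: int = 512) -> float:
    """Overlap coefficient O(f, g) = ∫ min(f, g) dv of two size
    distributions.

    Gaussian KDEs (Scott's rule) are evaluated on a shared grid spanning
    the union of both supports padded by three bandwidths; the integral
    is taken by trapezoidal quadrature and clipped to [0, 1].  Identical
    distributions give O ≈ 1, disjoint ones O ≈ 0.
    """
    f = np.asarray(samples_f, dtype=float)
    g = np.asarray(samples_g, dtype=float)
    if f.size < 10 or g.size < 10:
        raise ValueError("need at least 10 samples per distribution")
    kde_f = stats.gaussian_kde(f)
    kde_g = stats.gaussian_kde(g)
    h = max(
        kde_f.factor * f.std(ddof=1),
        kde_g.factor * g.std(ddof=1),
    )
    lo = min(f.min(), g.min()) - 3 * h
    hi = max(f.max(), g.max()) + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    overlap = np.trapezoid(np.minimum(kde_f(grid), kde_g(grid)), grid)
    return float(np.clip(overlap, 0.0, 1.0))


def _durations_events(
    records: Iterable[CellCycleRecord], phase: Literal["cycle", "mitosis"]
) -> tuple[np.ndarray, np.ndarray]:
    durations, events = [], []
    for r in records:
        mit, cyc = phase_durations(r)
        d = cyc if phase == "cycle" else mit
        if math.isnan(d):
            continue
        durations.append(d)
        events.append(not r.censored)
    return np.asarray(durations, dtype=float), np.asarray(events, dtype=bool)


def compare_durations(
    group_a: Iterable[CellCycleRecord],
    group_b: Iterable[CellCycleRecord],
    phase: Literal["cycle", "mitosis"] = "cycle",
) -> float:
    """Log-rank p-value for a duration difference between two
    populations, respecting censored cycles."""
    da, ea = _durations_events(group_a, phase)
    db, eb = _durations_events(group_b, phase)
    if da.size == 0 or db.size == 0:
        raise ValueError("both groups must contain records with the phase observed")
    if not ea.any() or not eb.any():
        raise ValueError("a group with only censored durations cannot be compared")
    res = logrank_test(da, db, event_observed_A=ea, event_observed_B=eb)
    return float(res.p_value)


def compare_locations(x, y, alpha: float = 0.05) -> tuple[str, float]:
    """Two-group location test under the same normality gate: Welch's t
    when both samples pass 3-of-4 normality, Mann–Whitney otherwise.

    Returns (test name, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if is_normal(x, alpha) and is_normal(y, alpha):
        return "welch_t", float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    return "mann_whitney", float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
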
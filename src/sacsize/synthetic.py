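"""Synthetic data with known ground truth for every downstream analysis.

Generates what the imaging pipeline would deliver: single-cycle area
trajectories sampled every ``dt`` minutes along the growth curve, a
corrupted copy carrying multiplicative measurement noise and isolated
segmentation spikes, cell-cycle record tables with censoring, and the
binomial mis-segregation counts and ESR fold-change profiles handled
elsewhere (:func:`sacsize.aneuploidy.simulate_misseg_counts`,
:func:`sacsize.proteome.simulate_esr_profile`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cyclestats import CellCycleRecord
from .growth import (
    CycleTimeModel,
    GrowthParams,
    draw_cycle_length,
    growth_curve,
    simulate_entry_sizes,
    time_at_size,
)
from .trajectories import SizeTrajectory

__all__ = [
    "CorruptionModel",
    "generate_trajectories",
    "generate_cycle_records",
    "generate_timer_records",
    "generate_sizer_records",
]


@dataclass(frozen=True)
class CorruptionModel:
    """Measurement-corruption parameters for synthetic trajectories.

    ``spike_probability``: chance per interior point of an isolated
    additive segmentation spike; ``spike_amplitude``: (low, high) of the
    spike magnitude in μm² (sign drawn at random); ``noise_cv``:
    multiplicative measurement noise CV; ``censor_prob``: chance per
    cycle of censoring (end of imaging / cell death).
    """

    spike_probability: float = 0.02
    spike_amplitude: tuple[float, float] = (10.0, 20.0)
    noise_cv: float = 0.01
    censor_prob: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.spike_probability <= 1.0:
            raise ValueError("spike_probability must lie in [0, 1]")
        if not 0.0 <= self.censor_prob <= 1.0:
            raise ValueError("censor_prob must lie in [0, 1]")
        lo, hi = self.spike_amplitude
        if not (math.isfinite(lo) and math.isfinite(hi)) or lo < 0 or hi < lo:
            raise ValueError("spike_amplitude must be a finite 0 <= low <= high pair")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


def _isolated_spike_positions(
    n_points: int, p: float, rng: np.random.Generator
) -> np.ndarray:
    """Interior indices for spikes, thinned so no two are adjacent
    (adjacent corrupted frames are rare in practice and would mimic a
    real size step)."""
    candidates = np.flatnonzero(rng.random(n_points) < p)
    candidates = candidates[(candidates > 0) & (candidates < n_points - 1)]
    keep: list[int] = []
    for idx in candidates:
        if not keep or idx - keep[-1] > 1:
            keep.append(int(idx))
    return np.asarray(keep, dtype=int)


def generate_trajectories(
    params: GrowthParams,
    model: CycleTimeModel,
    corruption: CorruptionModel,
    n_cells: int,
    dt: float = 10.0,
    rng: np.random.Generator | None = None,
    burn_in_cycles: int = 8,
    start_areas: np.ndarray | None = None,
) -> tuple[list[SizeTrajectory], list[SizeTrajectory], pd.DataFrame]:
    """Single-cycle area trajectories with a corrupted twin and truth.

    Each cell starts from a steady-state entry size of the given regime
    (``burn_in_cycles`` of division equilibrate the entry distribution)
    unless explicit ``start_areas`` are given — pass small sizes near A0
    to emulate gen0 cells released from a G1 arrest, which populate the
    lower size clusters the way a pooled per-condition group does.  The
    cell then grows along the curve for one drawn cycle, sampled every
    ``dt`` min.  The corrupted copy multiplies each point by
    (1 + noise) and adds isolated spikes.

    Returns ``(clean, corrupted, truth)`` where truth has one row per
    injected spike: cell_id, index, amplitude.
    """
    if rng is None:
        raise ValueError("a seeded numpy Generator must be supplied")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if start_areas is not None:
        entries = np.asarray(start_areas, dtype=float)
        if entries.size != n_cells:
            raise ValueError("start_areas must have one entry per cell")
    else:
        entries = simulate_entry_sizes(params, model, n_cells, burn_in_cycles, rng)[:, -1]
    condition = "sac" if model.regime == "sac_active" else "unperturbed"

    clean: list[SizeTrajectory] = []
    corrupted: list[SizeTrajectory] = []
    truth_rows: list[dict] = []
    for c in range(n_cells):
        tau0 = time_at_size(params, entries[c])
        T = draw_cycle_length(model, rng)
        n_pts = max(int(T // dt) + 1, 4)
        times = np.arange(n_pts) * dt
        areas = np.asarray(growth_curve(params, tau0 + times))
        cell_id = f"cell{c:04d}"
        clean.append(
            SizeTrajectory(times=times, areas=areas, cell_id=cell_id, condition=condition)
        )

        noisy = areas * (1.0 + rng.normal(0.0, corruption.noise_cv, n_pts))
        spikes = _isolated_spike_positions(n_pts, corruption.spike_probability, rng)
        for idx in spikes:
            lo, hi = corruption.spike_amplitude
            amp = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
            # keep areas physical and inside the clustered size range
            amp = max(amp, 1.0 - noisy[idx])
            noisy[idx] += amp
            truth_rows.append({"cell_id": cell_id, "index": int(idx), "amplitude": amp})
        corrupted.append(
            SizeTrajectory(times=times, areas=noisy, cell_id=cell_id, condition=condition)
        )
    truth = pd.DataFrame(truth_rows, columns=["cell_id", "index", "amplitude"])
    return clean, corrupted, truth


DEFAULT_MITOTIC_FRACTION = {"unperturbed": 0.3}
#: Non-mitotic duration (min) for SAC-active cycles: mean, SD of a
#: normal draw, independent of the arrest length.
DEFAULT_SAC_NONMITOTIC = (70.0, 10.0)


def generate_cycle_records(
    params: GrowthParams,
    models: dict[str, CycleTimeModel],
    n_cells: int,
    censor_prob: float = 0.0,
    rng: np.random.Generator | None = None,
    mitotic_fraction: dict[str, float] | None = None,
    sac_nonmitotic: tuple[float, float] = DEFAULT_SAC_NONMITOTIC,
    burn_in_cycles: int = 8,
) -> list[CellCycleRecord]:
    """Cell-cycle record tables with landmark times and curve sizes.

    For each regime in ``models``, ``n_cells`` cells start from the
    regime's steady entry-size distribution and draw a cycle of length C
    from the regime's distribution.  The split into phases differs by
    regime: unperturbed cycles spend a fixed fraction of C in mitosis
    (``mitotic_fraction``, default 0.3) — a timer-like mitosis — whereas
    SAC-active cycles spend an independently drawn non-mitotic time
    (``sac_nonmitotic``, Normal(70, 10) min by default) and the rest of
    C arrested in mitosis, since the checkpoint arrest and slippage time
    do not depend on how long interphase took.  80% of the non-mitotic
    time precedes mitotic entry, the remainder follows anaphase.

    Sizes A_BUD, A_PM, A_ANA are read off the growth curve at the
    landmark times.  With probability ``censor_prob`` the terminal
    landmarks (anaphase, re-budding) are unobserved and the record is
    flagged censored.
    """
    if rng is None:
        raise ValueError("a seeded numpy Generator must be supplied")
    frac = dict(DEFAULT_MITOTIC_FRACTION)
    if mitotic_fraction:
        frac.update(mitotic_fraction)

    records: list[CellCycleRecord] = []
    for regime, model in models.items():
        entries = simulate_entry_sizes(params, model, n_cells, burn_in_cycles, rng)[:, -1]
        C = draw_cycle_length(model, rng, size=n_cells)
        if regime == "sac_active":
            nm_mean, nm_sd = sac_nonmitotic
            NM = rng.normal(nm_mean, nm_sd, n_cells)
            NM = np.clip(NM, 1.0, 0.9 * C)
            M = C - NM
        else:
            M = frac.get(regime, DEFAULT_MITOTIC_FRACTION["unperturbed"]) * C
            NM = C - M
        t_pm_rel = 0.8 * NM
        for c in range(n_cells):
            tau0 = time_at_size(params, entries[c])
            censored = bool(rng.random() < censor_prob)
            rec = CellCycleRecord(
                cell_id=f"{regime}-{c:04d}",
                condition=regime,
                generation=1,
                t_bud=0.0,
                t_pm=t_pm_rel[c],
                t_ana=t_pm_rel[c] + M[c] if not censored else math.nan,
                t_next_bud=C[c] if not censored else math.nan,
                censored=censored,
                A_bud=float(growth_curve(params, tau0)),
                A_pm=float(growth_curve(params, tau0 + t_pm_rel[c])),
                A_ana=float(growth_curve(params, tau0 + t_pm_rel[c] + M[c]))
                if not censored
                else math.nan,
            )
            records.append(rec)
    return records


def generate_timer_records(
    n_cells: int,
    rng: np.random.Generator,
    growth_fold: float = 1.5,
    entry_mean: float = 60.0,
    entry_cv: float = 0.2,
    noise_sd: float = 0.0,
) -> list[CellCycleRecord]:
    """Pure-timer control: every cell multiplies its size by the same
    factor during mitosis (A_ANA = fold · A_PM), so the size-growth
    slope λ is 0 (no size control).  Optional noise perturbs G
    independently of entry size."""
    A_pm = entry_mean * np.exp(rng.normal(0.0, entry_cv, n_cells))
    G = math.log(growth_fold) + rng.normal(0.0, noise_sd, n_cells)
    A_ana = A_pm * np.exp(G)
    return [
        CellCycleRecord(
            cell_id=f"timer-{i:04d}",
            condition="timer",
            t_bud=0.0,
            A_pm=float(A_pm[i]),
            A_ana=float(A_ana[i]),
        )
        for i in range(n_cells)
    ]


def generate_sizer_records(
    n_cells: int,
    rng: np.random.Generator,
    exit_size: float = 90.0,
    entry_mean: float = 60.0,
    entry_cv: float = 0.2,
) -> list[CellCycleRecord]:
    """Perfect-sizer control: every cell leaves mitosis at the same size
    (A_ANA constant), so the size-growth slope λ is exactly −1."""
    A_pm = entry_mean * np.exp(rng.normal(0.0, entry_cv, n_cells))
    return [
        CellCycleRecord(
            cell_id=f"sizer-{i:04d}",
            condition="sizer",
            t_bud=0.0,
            A_pm=float(A_pm[i]),
            A_ana=float(exit_size),
        )
        for i in range(n_cells)
    ]
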
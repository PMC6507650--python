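"""Stochastic growth/division model for cells cycling with or without an
active spindle assembly checkpoint (SAC).

Single-cell area follows a logistic growth curve multiplied by a linear
term,

    A(t) = A0 * Amax * exp(r t) / (Amax + A0 * (exp(r t) - 1)) * (1 + (m/Amax) t),

which is exponential (~e^{rt}) for small t and approaches a straight line
of slope ``m`` for large t.  ``A0`` is the size at t = 0 and ``Amax`` sets
the size at which growth crosses over from exponential to linear.

Cell-cycle durations are phenomenological: unperturbed cells draw from a
normal distribution (mean 100 min, SD 10 min) while SAC-active cells draw
from a delayed exponential (200 min delay + exponential with mean
200 min), reflecting checkpoint slippage after a stochastic mitotic
arrest.  Division instantaneously halves the cell area, after which the
cell jumps back to the point on the growth curve corresponding to its new
size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "GrowthParams",
    "CycleTimeModel",
    "LineageTrace",
    "compute_growth_rate",
    "growth_curve",
    "time_at_size",
    "draw_cycle_length",
    "divide",
    "simulate_lineage",
    "simulate_entry_sizes",
    "simulate_withdrawal",
]


def compute_growth_rate(A0: float, Amax: float, T: float) -> float:
    """Calibrate the exponential rate r so that a cell starting at ``A0``
    doubles in one unperturbed cycle of length ``T`` (with m = 0):

        r = [ln(2 (Amax - A0)) - ln(Amax - 2 A0)] / T

    Requires Amax > 2*A0, otherwise doubling on the logistic branch is
    unattainable and the formula is undefined.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if Amax <= 2 * A0:
        raise ValueError(
            "invalid calibration: Amax must exceed 2*A0 for the cell to "
            "double on the logistic branch"
        )
    if A0 <= 0:
        raise ValueError("A0 must be positive")
    return (math.log(2 * (Amax - A0)) - math.log(Amax - 2 * A0)) / T


@dataclass(frozen=True)
class GrowthParams:
    """Growth-curve constants.

    Parameters
    ----------
    A0 : float
        Area at t = 0 (μm²).
    Amax : float
        Exponential-to-linear transition scale (μm²).
    r : float, optional
        Exponential growth rate (min⁻¹).  If omitted it is calibrated
        from (A0, Amax, T_unperturbed) via :func:`compute_growth_rate`.
    m : float
        Asymptotic linear slope (μm²·min⁻¹).  Not constrained by the
        doubling calibration; default 0.3 places the SAC-active steady
        entry size a few-fold above A0.
    T_unperturbed : float
        Reference unperturbed cycle length (min).
    """

    A0: float = 20.0
    Amax: float = 120.0
    r: float = field(default=None)  # type: ignore[assignment]
    m: float = 0.3
    T_unperturbed: float = 100.0

    def __post_init__(self) -> None:
        if self.A0 <= 0:
            raise ValueError("A0 must be positive")
        if self.Amax <= 2 * self.A0:
            raise ValueError("Amax must exceed 2*A0")
        if self.m < 0:
            raise ValueError("m must be non-negative")
        if self.T_unperturbed <= 0:
            raise ValueError("T_unperturbed must be positive")
        if self.r is None:
            object.__setattr__(
                self, "r", compute_growth_rate(self.A0, self.Amax, self.T_unperturbed)
            )
        if self.r <= 0:
            raise ValueError("r must be positive")

    def with_m(self, m: float) -> "GrowthParams":
        return replace(self, m=m)


def growth_curve(params: GrowthParams, t):
    """Evaluate the combined logistic x linear growth curve A(t).

    ``t`` may be a scalar or array of times (min, >= 0); returns area(s)
    in μm².  A(0) = A0 and the curve is strictly increasing.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    e = np.exp(params.r * t_arr)
    logistic = params.A0 * params.Amax * e / (params.Amax + params.A0 * (e - 1.0))
    out = logistic * (1.0 + (params.m / params.Amax) * t_arr)
    return out.item() if np.isscalar(t) or np.ndim(t) == 0 else out


def time_at_size(params: GrowthParams, A: float) -> float:
    """Invert the growth curve: the time t >= 0 with A(t) = A.

    The curve is strictly monotone, so the inverse is found by bracketed
    root search.  For m = 0 the attainable range is [A0, Amax); for m > 0
    any A >= A0 is reachable.
    """
    if A < params.A0:
        raise ValueError(f"size {A} below curve origin A0={params.A0}")
    if params.m == 0 and A >= params.Amax:
        raise ValueError(f"size {A} unreachable: curve saturates at Amax={params.Amax}")
    if A == params.A0:
        return 0.0
    hi = params.T_unperturbed
    while growth_curve(params, hi) < A:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - guards pathological parameters
            raise RuntimeError("failed to bracket time_at_size")
    return brentq(lambda t: growth_curve(params, t) - A, 0.0, hi, xtol=1e-12, rtol=1e-15)


@dataclass(frozen=True)
class CycleTimeModel:
    """Regime-labelled cell-cycle-length distribution.

    ``unperturbed``: Normal(mean, sd) truncated to positive durations by
    resampling.  ``sac_active``: delay + Exponential(mean) — a fixed
    minimum arrest plus a memoryless slippage time.
    """

    regime: Literal["unperturbed", "sac_active"]
    mean: float
    sd: float = 0.0
    delay: float = 0.0

    def __post_init__(self) -> None:
        if self.regime not in ("unperturbed", "sac_active"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.mean <= 0:
            raise ValueError("mean must be positive")
        if self.regime == "unperturbed" and self.sd <= 0:
            raise ValueError("sd must be positive for the unperturbed regime")
        if self.regime == "sac_active" and self.delay <= 0:
            raise ValueError("delay must be positive for the sac_active regime")

    @classmethod
    def unperturbed(cls, mean: float = 100.0, sd: float = 10.0) -> "CycleTimeModel":
        return cls(regime="unperturbed", mean=mean, sd=sd)

    @classmethod
    def sac_active(cls, mean: float = 200.0, delay: float = 200.0) -> "CycleTimeModel":
        return cls(regime="sac_active", mean=mean, delay=delay)


def draw_cycle_length(model: CycleTimeModel, rng: np.random.Generator, size=None):
    """Draw cycle duration(s) in minutes from the regime's distribution.

    Negative normal draws are rejected and resampled (astronomically rare
    at mean 100, SD 10) so the stated mean/SD are preserved.
    """
    if size is None:
        return float(draw_cycle_length(model, rng, size=1)[0])
    if model.regime == "unperturbed":
        out = rng.normal(model.mean, model.sd, size=size)
        bad = out <= 0
        while np.any(bad):
            out[bad] = rng.normal(model.mean, model.sd, size=int(bad.sum()))
            bad = out <= 0
        return out
    return model.delay + rng.exponential(model.mean, size=size)


def divide(params: GrowthParams, pre_area: float) -> tuple[float, float]:
    """Instantaneous division: halve the area and return
    ``(post_area, restart_time)`` where ``restart_time`` is the position
    on the growth curve corresponding to the halved size.

    If the halved size falls below A0 (impossible with the default
    parameters) the restart is clamped to the curve origin with a
    warning.
    """
    post = pre_area / 2.0
    if post < params.A0:
        warnings.warn(
            f"post-division size {post:.3g} below A0={params.A0}; clamping to curve origin",
            RuntimeWarning,
            stacklevel=2,
        )
        return params.A0, 0.0
    return post, time_at_size(params, post)


@dataclass
class LineageTrace:
    """Simulated single-lineage trace.

    ``samples``: tidy frame with columns time_min, area_um2, regime,
    generation.  ``divisions``: one row per division with time_min,
    pre_area_um2, post_area_um2, regime (regime active at the division,
    i.e. governing the next drawn duration).
    """

    samples: pd.DataFrame
    divisions: pd.DataFrame


def _regime_at(schedule: Sequence[tuple[float, CycleTimeModel]], t: float) -> CycleTimeModel:
    active = schedule[0][1]
    for switch_time, model in schedule:
        if t >= switch_time:
            active = model
        else:
            break
    return active


def simulate_lineage(
    params: GrowthParams,
    regime_schedule: Sequence[tuple[float, CycleTimeModel]],
    n_cycles: int,
    dt: float = 10.0,
    rng: np.random.Generator | None = None,
    start_area: float | None = None,
    growth: Literal["combined", "exponential"] = "combined",
) -> LineageTrace:
    """Simulate one lineage for ``n_cycles`` consecutive cycles.

    ``regime_schedule`` is a non-decreasing list of ``(switch_time,
    CycleTimeModel)``; the first entry must be active at t = 0 (its
    switch_time <= 0).  At each division the duration of the *next* cycle
    is drawn from the regime active at that instant.  Between divisions
    the area follows the growth curve from the cell's current curve
    position (``growth="combined"``) or grows purely exponentially at
    rate r (``growth="exponential"``, the divergent control).

    The trace records the area at every multiple of ``dt`` plus one row
    per division event.
    """
    if rng is None:
        raise ValueError("a seeded numpy Generator must be supplied")
    if dt <= 0:
        raise ValueError("dt must be positive")
    switches = [s for s, _ in regime_schedule]
    if any(b < a for a, b in zip(switches, switches[1:])):
        raise ValueError("schedule switch times must be non-decreasing")
    if switches[0] > 0:
        raise ValueError("first schedule entry must be active at t=0")

    area = params.A0 if start_area is None else float(start_area)
    tau = time_at_size(params, area)  # position on the growth curve
    t = 0.0
    times, areas, regimes, gens = [], [], [], []
    div_rows = []
    next_sample = 0.0

    for gen in range(n_cycles):
        model = _regime_at(regime_schedule, t)
        T = draw_cycle_length(model, rng)
        t_div = t + T
        while next_sample < t_div:
            elapsed = next_sample - t
            if growth == "combined":
                a = growth_curve(params, tau + elapsed)
            else:
                a = area * math.exp(params.r * elapsed)
            times.append(next_sample)
            areas.append(a)
            regimes.append(model.regime)
            gens.append(gen)
            next_sample += dt
        if growth == "combined":
            pre = growth_curve(params, tau + T)
            area, tau = divide(params, pre)
        else:
            pre = area * math.exp(params.r * T)
            area = pre / 2.0
        div_rows.append(
            {
                "time_min": t_div,
                "pre_area_um2": pre,
                "post_area_um2": area,
                "regime": _regime_at(regime_schedule, t_div).regime,
            }
        )
        t = t_div

    samples = pd.DataFrame(
        {"time_min": times, "area_um2": areas, "regime": regimes, "generation": gens}
    )
    divisions = pd.DataFrame(
        div_rows, columns=["time_min", "pre_area_um2", "post_area_um2", "regime"]
    )
    return LineageTrace(samples=samples, divisions=divisions)


def simulate_entry_sizes(
    params: GrowthParams,
    model: CycleTimeModel,
    n_cells: int,
    n_cycles: int,
    rng: np.random.Generator,
    growth: Literal["combined", "exponential"] = "combined",
    start_area: float | None = None,
) -> np.ndarray:
    """Post-division (entry) sizes for independent lineages.

    Returns an array of shape ``(n_cells, n_cycles)``: column k holds the
    size right after the (k+1)-th division for each cell.  All cells
    start at ``start_area`` (default A0) and draw cycle lengths from one
    fixed regime.
    """
    if n_cells < 1 or n_cycles < 1:
        raise ValueError("n_cells and n_cycles must be >= 1")
    a0 = params.A0 if start_area is None else float(start_area)
    entries = np.empty((n_cells, n_cycles))
    if growth == "exponential":
        area = np.full(n_cells, a0)
        for k in range(n_cycles):
            T = draw_cycle_length(model, rng, size=n_cells)
            area = area * np.exp(params.r * T) / 2.0
            entries[:, k] = area
        return entries
    tau = np.full(n_cells, time_at_size(params, a0))
    for k in range(n_cycles):
        T = draw_cycle_length(model, rng, size=n_cells)
        pre = growth_curve(params, tau + T)
        post = pre / 2.0
        below = post < params.A0
        if np.any(below):  # pragma: no cover - cannot occur with defaults
            post[below] = params.A0
        entries[:, k] = post
        tau = np.array([time_at_size(params, a) for a in post])
    return entries


def simulate_withdrawal(
    params: GrowthParams,
    n_cells: int,
    n_cycles_before: int,
    n_cycles_after: int,
    rng: np.random.Generator,
    sac_model: CycleTimeModel | None = None,
    unperturbed_model: CycleTimeModel | None = None,
) -> pd.DataFrame:
    """In-silico checkpoint-withdrawal experiment.

    Each of ``n_cells`` lineages cycles ``n_cycles_before`` times in the
    SAC-active regime (reaching the large steady entry-size
    distribution); at time 0 the duration distribution switches to the
    unperturbed one and ``n_cycles_after`` further cycles are simulated.

    Returns a tidy frame (cell, cycle, entry_area_um2) where cycle 0 is
    the last SAC-active entry size (the pre-withdrawal steady state) and
    cycles 1..n_cycles_after are the post-withdrawal entries.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    sac = sac_model or CycleTimeModel.sac_active()
    unp = unperturbed_model or CycleTimeModel.unperturbed()

    sac_entries = simulate_entry_sizes(params, sac, n_cells, n_cycles_before, rng)
    start = sac_entries[:, -1]
    rows = [
        pd.DataFrame(
            {"cell": np.arange(n_cells), "cycle": 0, "entry_area_um2": start}
        )
    ]
    if n_cycles_after > 0:
        tau = np.array([time_at_size(params, a) for a in start])
        for k in range(1, n_cycles_after + 1):
            T = draw_cycle_length(unp, rng, size=n_cells)
            post = growth_curve(params, tau + T) / 2.0
            post = np.maximum(post, params.A0)
            tau = np.array([time_at_size(params, a) for a in post])
            rows.append(
                pd.DataFrame(
                    {"cell": np.arange(n_cells), "cycle": k, "entry_area_um2": post}
                )
            )
    return pd.concat(rows, ignore_index=True)
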
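"""Filtering, smoothing and derivative estimation for single-cell size
trajectories.

Time-lapse segmentation occasionally produces isolated spikes in the
extracted cell area (segmentation errors, altered phase contrast).  The
filter works on the local size variations ΔA_i = A_{i+1} − A_i: pooled
(A_i, ΔA_i) pairs are split into three size clusters (0–40, 40–80,
80–120 μm²) and, per cluster, Tukey fences Q1 − 1.5·IQR / Q3 + 1.5·IQR
bound the admissible variation.  Points whose variations violate the
fences are replaced by the mean of their two neighbours, iterating at
most ``max_iter`` times.  Adjusted trajectories are then smoothed with a
centered moving average (window 3 for unperturbed conditions, 8 for
SAC-active ones) before the local growth rate dA/dt is taken by central
finite differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SizeTrajectory",
    "ClusterThresholds",
    "DEFAULT_CLUSTER_EDGES",
    "PIXEL_AREA_UM2",
    "local_variations",
    "fit_thresholds",
    "adjust_trajectory",
    "smooth",
    "smoothing_window",
    "local_growth_rate",
    "bin_means",
    "mean_trajectory",
    "pixels_to_area",
    "trajectories_from_frame",
    "trajectories_to_frame",
]

#: Size-cluster edges for the outlier fences (μm²).
DEFAULT_CLUSTER_EDGES: tuple[float, ...] = (0.0, 40.0, 80.0, 120.0)

#: Pixel-to-area conversion for the imaging setup (1 px ~ 0.05 μm²).
PIXEL_AREA_UM2 = 0.05


@dataclass
class SizeTrajectory:
    """One cell's area time series.

    ``condition`` is one of ``gen0-unperturbed``, ``unperturbed``,
    ``gen0-sac`` or ``sac`` (free-form labels are accepted; SAC-like
    conditions are recognised by the substring ``"sac"``).
    """

    times: np.ndarray
    areas: np.ndarray
    cell_id: str = ""
    condition: str = "unperturbed"
    adjusted_flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    clb2: np.ndarray | None = None
    censored: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.times.shape != self.areas.shape:
            raise ValueError("times and areas must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.areas <= 0):
            raise ValueError("areas must be positive")
        if self.adjusted_flags is None:
            self.adjusted_flags = np.zeros(self.times.size, dtype=bool)
        else:
            self.adjusted_flags = np.asarray(self.adjusted_flags, dtype=bool)

    def __len__(self) -> int:
        return self.times.size


def pixels_to_area(pixels) -> float | np.ndarray:
    """Convert a segmented pixel count to μm² (1 px ~ 0.05 μm²)."""
    arr = np.asarray(pixels, dtype=float)
    if np.any(arr < 0):
        raise ValueError("pixel counts must be non-negative")
    out = PIXEL_AREA_UM2 * arr
    return out.item() if np.ndim(pixels) == 0 else out


def local_variations(traj: SizeTrajectory | np.ndarray) -> np.ndarray:
    """ΔA_i = A_{i+1} − A_i (length N−1)."""
    areas = traj.areas if isinstance(traj, SizeTrajectory) else np.asarray(traj, float)
    if areas.size < 2:
        raise ValueError("need at least two points for local variations")
    return np.diff(areas)


@dataclass(frozen=True)
class ClusterThresholds:
    """Per-size-cluster Tukey fences on ΔA.

    ``bounds[k]`` is ``(lower, upper)`` for the cluster
    ``edges[k] < A <= edges[k+1]`` (first cluster includes A <= edges[1]),
    or ``None`` when the cluster held too few points to fit.  Points
    falling outside every cluster (A above the last edge) are never
    flagged.
    """

    edges: tuple[float, ...] = DEFAULT_CLUSTER_EDGES
    bounds: tuple[tuple[float, float] | None, ...] = ()

    def cluster_index(self, area: float) -> int | None:
        if area > self.edges[-1]:
            return None
        for k in range(len(self.edges) - 1):
            if area <= self.edges[k + 1]:
                return k
        return None  # pragma: no cover

    def violates(self, area: float, delta: float) -> bool:
        """Is the pair (A_i, ΔA_i) outside its cluster's fences?"""
        k = self.cluster_index(area)
        if k is None or k >= len(self.bounds) or self.bounds[k] is None:
            return False
        lo, hi = self.bounds[k]
        return delta < lo or delta > hi


def fit_thresholds(
    trajs: Iterable[SizeTrajectory],
    edges: Sequence[float] = DEFAULT_CLUSTER_EDGES,
    min_points: int = 4,
) -> ClusterThresholds:
    """Fit per-cluster ΔA fences on the pooled group distribution.

    Each (A_i, ΔA_i) pair across all trajectories is assigned to the
    cluster of its A_i; per cluster the fences are Q1 − 1.5·IQR and
    Q3 + 1.5·IQR with linearly interpolated quartiles (numpy's default,
    type-7).  Clusters with fewer than ``min_points`` pairs stay unset.
    """
    edges = tuple(float(e) for e in edges)
    pooled_a: list[np.ndarray] = []
    pooled_d: list[np.ndarray] = []
    for traj in trajs:
        if len(traj) < 2:
            continue
        pooled_a.append(traj.areas[:-1])
        pooled_d.append(np.diff(traj.areas))
    if not pooled_a:
        raise ValueError("no trajectories with >= 2 points supplied")
    a = np.concatenate(pooled_a)
    d = np.concatenate(pooled_d)

    bounds: list[tuple[float, float] | None] = []
    for k in range(len(edges) - 1):
        lo_edge, hi_edge = edges[k], edges[k + 1]
        mask = (a <= hi_edge) if k == 0 else (a > lo_edge) & (a <= hi_edge)
        dk = d[mask]
        if dk.size < min_points:
            bounds.append(None)
            continue
        q1, q3 = np.quantile(dk, [0.25, 0.75])
        iqr = q3 - q1
        bounds.append((q1 - 1.5 * iqr, q3 + 1.5 * iqr))
    return ClusterThresholds(edges=edges, bounds=tuple(bounds))


def adjust_trajectory(
    traj: SizeTrajectory,
    thr: ClusterThresholds,
    max_iter: int = 10,
    flag_mode: Literal["both", "either", "forward"] = "both",
) -> tuple[SizeTrajectory, int]:
    """Replace outlier points by the mean of their two neighbours.

    An interior point A_i is an outlier when its local variations
    violate the cluster fences; which variations count is set by
    ``flag_mode``:

    - ``"both"`` (default): both the incoming ΔA_{i−1} and the outgoing
      ΔA_i violate — the signature of an isolated spike.  A single spike
      is repaired in one pass without touching its clean neighbours.
    - ``"either"``: one violating side suffices (more aggressive; the
      neighbours of a spike are transiently replaced too).
    - ``"forward"``: only the outgoing ΔA_i is considered, matching the
      pairing of ΔA_i with A_i in the cluster scatter.

    Each pair (A_j, ΔA_j) is judged against the fences of A_j's own
    cluster; pairs in unset clusters never violate.  Replacement sweeps
    left to right, updating in place, and the whole sweep repeats until
    no point is replaced or ``max_iter`` sweeps have run.  Endpoints are
    never replaced.  Returns the adjusted trajectory (replaced points
    flagged) and the number of sweeps that performed a replacement.
    """
    areas = traj.areas.copy()
    flags = traj.adjusted_flags.copy()
    n = areas.size
    n_sweeps = 0
    if n < 3:
        return replace(traj, areas=areas, adjusted_flags=flags), 0

    for _ in range(max_iter):
        changed = False
        for i in range(1, n - 1):
            d_in = areas[i] - areas[i - 1]
            d_out = areas[i + 1] - areas[i]
            v_in = thr.violates(areas[i - 1], d_in)
            v_out = thr.violates(areas[i], d_out)
            if flag_mode == "both":
                bad = v_in and v_out
            elif flag_mode == "either":
                bad = v_in or v_out
            else:
                bad = v_out
            if bad:
                areas[i] = 0.5 * (areas[i - 1] + areas[i + 1])
                flags[i] = True
                changed = True
        if changed:
            n_sweeps += 1
        else:
            break
    return replace(traj, areas=areas, adjusted_flags=flags), n_sweeps


def smoothing_window(condition: str) -> int:
    """Default moving-average window: 8 for SAC-active conditions,
    3 for unperturbed ones."""
    return 8 if "sac" in condition.lower() else 3


def smooth(traj: SizeTrajectory, window: int | None = None) -> SizeTrajectory:
    """Centered moving average with a window shrinking at the edges.

    ``window=None`` picks the condition default (3 unperturbed / 8 SAC).
    Odd windows are symmetric; even windows take one extra point on the
    trailing side.  Near the edges the window shrinks to the available
    points.  ``window=1`` is the identity.
    """
    w = smoothing_window(traj.condition) if window is None else int(window)
    n = len(traj)
    if w < 1:
        raise ValueError("window must be >= 1")
    if w > n:
        raise ValueError(f"window {w} exceeds trajectory length {n}")
    if w == 1:
        return replace(traj, areas=traj.areas.copy())
    half_l = (w - 1) // 2
    half_r = w // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half_l)
        hi = min(n, i + half_r + 1)
        out[i] = traj.areas[lo:hi].mean()
    return replace(traj, areas=out)


def local_growth_rate(traj: SizeTrajectory) -> np.ndarray:
    """First derivative dA/dt by central finite differences.

    Interior points use (A_{i+1} − A_{i−1}) / (t_{i+1} − t_{i−1});
    endpoints fall back to one-sided differences.  Actual time gaps are
    used; non-uniform spacing triggers a warning but not an error.
    """
    if len(traj) < 3:
        raise ValueError("need at least three points for central differences")
    t, a = traj.times, traj.areas
    gaps = np.diff(t)
    if not np.allclose(gaps, gaps[0], rtol=1e-6):
        warnings.warn("non-uniform time spacing; using actual gaps", stacklevel=2)
    dadt = np.empty(len(traj))
    dadt[1:-1] = (a[2:] - a[:-2]) / (t[2:] - t[:-2])
    dadt[0] = (a[1] - a[0]) / (t[1] - t[0])
    dadt[-1] = (a[-1] - a[-2]) / (t[-1] - t[-2])
    return dadt


def bin_means(x, y, bin_width: float) -> pd.DataFrame:
    """Bin y against x in half-open windows [k·w, (k+1)·w).

    Returns one row per non-empty bin: bin index, mean x, mean y, count.
    The 10 μm² windows of the size/growth-rate analysis and the 70 or
    100 a.u. Clb2 windows are both expressed through ``bin_width``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    idx = np.floor(x / bin_width).astype(int)
    frame = pd.DataFrame({"bin": idx, "x": x, "y": y})
    out = (
        frame.groupby("bin", sort=True)
        .agg(x_mean=("x", "mean"), y_mean=("y", "mean"), n=("x", "size"))
        .reset_index()
    )
    return out


def mean_trajectory(
    trajs: Iterable[SizeTrajectory], min_support: int = 5
) -> pd.DataFrame:
    """Population mean size trajectory over a shared relative time grid.

    Trajectories are aligned on their own start (time 0 = first frame);
    only timepoints where *strictly more than* ``min_support``
    trajectories contribute are kept.  Returns columns time_min,
    mean_area_um2, n.
    """
    rows = []
    for traj in trajs:
        rel = traj.times - traj.times[0]
        rows.append(pd.DataFrame({"time_min": rel, "area_um2": traj.areas}))
    if not rows:
        return pd.DataFrame(columns=["time_min", "mean_area_um2", "n"])
    pooled = pd.concat(rows, ignore_index=True)
    agg = (
        pooled.groupby("time_min", sort=True)
        .agg(mean_area_um2=("area_um2", "mean"), n=("area_um2", "size"))
        .reset_index()
    )
    return agg[agg["n"] > min_support].reset_index(drop=True)


def trajectories_from_frame(frame: pd.DataFrame) -> list[SizeTrajectory]:
    """Build trajectories from a tidy table.

    Expected columns: cell_id, condition, time_min, and either area_um2
    or area_px (converted at 0.05 μm²/px); optional clb2_au and
    censored.  One trajectory per cell_id, rows sorted by time.
    """
    if "area_um2" not in frame.columns and "area_px" not in frame.columns:
        raise ValueError("table must contain area_um2 or area_px")
    out = []
    for cell_id, grp in frame.groupby("cell_id", sort=False):
        grp = grp.sort_values("time_min")
        areas = (
            grp["area_um2"].to_numpy()
            if "area_um2" in grp.columns
            else pixels_to_area(grp["area_px"].to_numpy())
        )
        out.append(
            SizeTrajectory(
                times=grp["time_min"].to_numpy(),
                areas=areas,
                cell_id=str(cell_id),
                condition=str(grp["condition"].iloc[0]) if "condition" in grp.columns else "unperturbed",
                clb2=grp["clb2_au"].to_numpy() if "clb2_au" in grp.columns else None,
                censored=bool(grp["censored"].iloc[0]) if "censored" in grp.columns else False,
            )
        )
    return out


def trajectories_to_frame(trajs: Iterable[SizeTrajectory]) -> pd.DataFrame:
    """Tidy table (cell_id, condition, frame, time_min, area_um2,
    adjusted) for writing as delimited text."""
    rows = []
    for traj in trajs:
        for k in range(len(traj)):
            rows.append(
                {
                    "cell_id": traj.cell_id,
                    "condition": traj.condition,
                    "frame": k,
                    "time_min": traj.times[k],
                    "area_um2": traj.areas[k],
                    "adjusted": bool(traj.adjusted_flags[k]),
                }
            )
    return pd.DataFrame(rows)
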
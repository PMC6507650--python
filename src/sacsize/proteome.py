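"""Stress-response-intensity scoring and clustering preparation for
environmental-stress-response (ESR) comparisons.

The ESR is a stereotyped yeast expression program with defined induced
and repressed gene sets.  Given log2 fold changes x_i over the induced
genes and y_j over the repressed genes, the normalized stress response
intensity is

    SRI = [Σ x_i + Σ (−y_j)] / [Σ |x_i| + Σ |y_j|]  ∈ [−1, 1],

reaching +1 exactly when every induced gene is up and every repressed
gene is down, and −1 for the exact sign reversal.  Profiles destined for
hierarchical clustering are z-normalized per sample and compared with
the correlation distance d = 1 − Spearman ρ under complete linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "FoldChangeProfile",
    "sri",
    "znormalize",
    "correlation_distance_matrix",
    "complete_linkage",
    "simulate_esr_profile",
]

ESR_CLASSES = ("induced", "repressed", "unrelated")


@dataclass
class FoldChangeProfile:
    """Gene-wise log2 fold changes with ESR class annotations."""

    genes: np.ndarray
    log2fc: np.ndarray
    esr_class: np.ndarray
    sample: str = ""

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes)
        self.log2fc = np.asarray(self.log2fc, dtype=float)
        self.esr_class = np.asarray(self.esr_class)
        if not (self.genes.size == self.log2fc.size == self.esr_class.size):
            raise ValueError("genes, log2fc and esr_class must align")
        if not np.all(np.isfinite(self.log2fc)):
            raise ValueError("fold changes must be finite")
        unknown = set(np.unique(self.esr_class)) - set(ESR_CLASSES)
        if unknown:
            raise ValueError(f"unknown ESR classes: {sorted(unknown)}")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, sample: str = "") -> "FoldChangeProfile":
        """Build from a table with columns gene, log2fc, esr_class."""
        return cls(
            genes=frame["gene"].to_numpy(),
            log2fc=frame["log2fc"].to_numpy(),
            esr_class=frame["esr_class"].to_numpy(),
            sample=sample,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.genes, "log2fc": self.log2fc, "esr_class": self.esr_class}
        )


def sri(profile: FoldChangeProfile) -> float:
    """Normalized stress response intensity of one sample.

    Only ESR-annotated genes enter; genes of class ``unrelated`` are
    ignored.  Undefined (rejected) when every ESR fold change is zero.
    """
    x = profile.log2fc[profile.esr_class == "induced"]
    y = profile.log2fc[profile.esr_class == "repressed"]
    if x.size == 0 or y.size == 0:
        raise ValueError("need at least one induced and one repressed gene")
    denom = np.abs(x).sum() + np.abs(y).sum()
    if denom == 0:
        raise ValueError("all ESR fold changes are zero: SRI undefined")
    return float((x.sum() - y.sum()) / denom)


def znormalize(values) -> np.ndarray:
    """Standardize to mean 0, sample SD 1 (ddof=1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero SD: cannot standardize a constant vector")
    return (v - v.mean()) / sd


def correlation_distance_matrix(profiles) -> np.ndarray:
    """Pairwise correlation distances d = 1 − Spearman ρ between
    samples.

    ``profiles`` is an (n_samples, n_genes) array (or list of vectors on
    a shared gene set).  The result is symmetric with zero diagonal and
    entries in [0, 2]; it is the input to complete-linkage clustering.
    """
    mat = np.asarray(profiles, dtype=float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need >= 2 profiles on a shared gene set")
    if mat.shape[1] < 3:
        raise ValueError("need >= 3 genes")
    if np.any(mat.std(axis=1) == 0):
        raise ValueError("constant profile: rank correlation undefined")
    rho = stats.spearmanr(mat.T).statistic
    rho = np.atleast_2d(rho)
    if rho.shape == (1, 1):  # spearmanr collapses the 2-sample case
        r = float(rho[0, 0])
        rho = np.array([[1.0, r], [r, 1.0]])
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    return d


def complete_linkage(distance_matrix: np.ndarray) -> np.ndarray:
    """Agglomerate a precomputed distance matrix with complete linkage;
    returns the scipy linkage matrix."""
    return linkage(squareform(distance_matrix, checks=False), method="complete")


def simulate_esr_profile(
    strength: float,
    n_induced: int,
    n_repressed: int,
    n_unrelated: int,
    noise_sd: float,
    rng: np.random.Generator,
    sample: str = "synthetic",
) -> FoldChangeProfile:
    """Synthetic ESR-structured fold-change profile.

    Induced genes draw from N(+strength, noise_sd), repressed from
    N(−strength, noise_sd), unrelated from N(0, noise_sd).  ``strength``
    in log2 units; strength 0 is the null profile.
    """
    if min(n_induced, n_repressed, n_unrelated) < 0 or n_induced < 1 or n_repressed < 1:
        raise ValueError("need n_induced, n_repressed >= 1 and n_unrelated >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    fc = np.concatenate(
        [
            rng.normal(strength, noise_sd, n_induced),
            rng.normal(-strength, noise_sd, n_repressed),
            rng.normal(0.0, noise_sd, n_unrelated),
        ]
    )
    classes = np.concatenate(
        [
            np.repeat("induced", n_induced),
            np.repeat("repressed", n_repressed),
            np.repeat("unrelated", n_unrelated),
        ]
    )
    genes = np.array([f"g{i:05d}" for i in range(fc.size)])
    return FoldChangeProfile(genes=genes, log2fc=fc, esr_class=classes, sample=sample)
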
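"""Pairwise linearized F_ST distances and SMACOF multidimensional scaling.

Population distances are AMOVA-based pairwise Phi_ST computed from
haplogroup (or haplotype) frequencies with 0/1 inter-haplotype distances —
a pure frequency statistic — then linearized with Slatkin's transform
Phi/(1 - Phi). Ordination is metric MDS by stress majorization (Guttman
transform) from a classical-scaling start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import FrequencyTable

#: Cap applied to the linearized distance when Phi_ST = 1.
LINEARIZED_CAP = 1e6


def pairwise_phist(counts_1: Sequence[int], counts_2: Sequence[int]) -> float:
    """AMOVA Phi_ST between two populations from category counts.

    With 0/1 distances between haplotypes, the within-population sum of
    squared deviations is SSD_g = (n_g/2)(1 - sum_i p_gi^2), the total is
    SSD_T = (N/2)(1 - sum_i P_i^2) over pooled frequencies, and
    Phi_ST = sigma_a^2 / (sigma_a^2 + sigma_w^2) from the usual variance
    components. Negative estimates are truncated to 0.
    """
    c1 = np.asarray(counts_1, dtype=float)
    c2 = np.asarray(counts_2, dtype=float)
    if c1.shape != c2.shape:
        raise ValueError("count vectors must share a category universe")
    if (c1 < 0).any() or (c2 < 0).any():
        raise ValueError("counts must be non-negative")
    n1, n2 = c1.sum(), c2.sum()
    if n1 == 0 or n2 == 0:
        raise ValueError("both populations must be non-empty")
    N = n1 + n2
    p1, p2 = c1 / n1, c2 / n2
    P = (c1 + c2) / N

    ssd_1 = n1 / 2.0 * (1.0 - float(np.sum(p1**2)))
    ssd_2 = n2 / 2.0 * (1.0 - float(np.sum(p2**2)))
    ssd_w = ssd_1 + ssd_2
    ssd_t = N / 2.0 * (1.0 - float(np.sum(P**2)))
    ssd_a = ssd_t - ssd_w

    sigma_w = ssd_w / (N - 2.0) if N > 2 else 0.0
    n_c = (N - (n1**2 + n2**2) / N)  # / (G - 1) with G = 2
    sigma_a = (ssd_a - sigma_w) / n_c if n_c > 0 else 0.0

    denom = sigma_a + sigma_w
    if denom <= 0:
        return 0.0
    phi = sigma_a / denom
    return float(min(1.0, max(0.0, phi)))


def linearize(phi: float) -> float:
    """Slatkin's transform D = Phi/(1 - Phi); Phi = 1 is capped."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"Phi_ST must be in [0, 1], got {phi}")
    if phi >= 1.0:
        return LINEARIZED_CAP
    return phi / (1.0 - phi)


@dataclass
class DistanceMatrix:
    """A symmetric non-negative distance matrix with population labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("matrix must be symmetric")
        if (self.values < 0).any() or not np.allclose(np.diag(self.values), 0):
            raise ValueError("matrix must be non-negative with zero diagonal")

    def __len__(self) -> int:
        return len(self.labels)


def distance_matrix(freqs: FrequencyTable) -> DistanceMatrix:
    """All pairwise linearized Phi_ST distances between populations."""
    pops = freqs.populations
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    if (freqs.n_g == 0).any():
        empty = list(freqs.n_g[freqs.n_g == 0].index)
        raise ValueError(f"populations with zero sample size: {empty}")
    n = len(pops)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = linearize(
                pairwise_phist(
                    freqs.population_counts(pops[i]),
                    freqs.population_counts(pops[j]),
                )
            )
            values[i, j] = values[j, i] = d
    return DistanceMatrix(list(pops), values)


@dataclass
class MDSConfiguration:
    """An MDS embedding with its normalized stress-1 trajectory."""

    labels: list[str]
    coordinates: np.ndarray
    stress: float
    iterations: int
    stress_history: list[float] = field(default_factory=list)


def _stress1(X: np.ndarray, delta: np.ndarray) -> float:
    d = _euclidean(X)
    iu = np.triu_indices(len(X), k=1)
    num = float(np.sum((delta[iu] - d[iu]) ** 2))
    den = float(np.sum(delta[iu] ** 2))
    return np.sqrt(num / den) if den > 0 else 0.0


def _euclidean(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    return np.sqrt(np.sum(diff**2, axis=-1))


def _torgerson(delta: np.ndarray, dims: int) -> np.ndarray:
    n = len(delta)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (delta**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dims]
    w_top = np.clip(w[order], 0.0, None)
    return V[:, order] * np.sqrt(w_top)


def smacof_mds(
    D: DistanceMatrix,
    dims: int = 2,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: Optional[int] = None,
) -> MDSConfiguration:
    """Metric MDS by stress majorization.

    Initializes with classical (Torgerson) scaling, then iterates the
    unweighted Guttman transform until the decrease in normalized stress-1
    falls below ``tol``. Raw stress is non-increasing under majorization, so
    the recorded stress-1 trajectory is monotone. The seed is used only when
    the Torgerson start is degenerate (e.g. an all-zero matrix).
    """
    delta = D.values
    n = len(D)
    if dims >= n:
        raise ValueError(f"dims={dims} must be < number of populations ({n})")
    X = _torgerson(delta, dims)
    if not np.any(X):  # degenerate start: all eigenvalues <= 0
        rng = np.random.default_rng(seed)
        X = rng.normal(scale=1e-3, size=(n, dims))
    X = X - X.mean(axis=0)

    history = [_stress1(X, delta)]
    for it in range(1, max_iter + 1):
        d = _euclidean(X)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, delta / d, 0.0)
        np.fill_diagonal(ratio, 0.0)
        B = -ratio
        np.fill_diagonal(B, ratio.sum(axis=1))
        X = (B @ X) / n
        X = X - X.mean(axis=0)
        history.append(_stress1(X, delta))
        if history[-2] - history[-1] < tol:
            break
    return MDSConfiguration(
        labels=list(D.labels),
        coordinates=X,
        stress=history[-1],
        iterations=len(history) - 1,
        stress_history=history,
    )
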
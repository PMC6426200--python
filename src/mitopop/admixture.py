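"""Weighted-least-squares admixture from haplogroup frequency vectors.

Estimates the mixing proportions m_k with which parental populations
contributed to a hybrid population by minimizing the weighted squared
deviation between the hybrid's haplogroup frequency vector and a convex
combination of the parental vectors (Long's WLS formulation). The sum
constraint sum(m) = 1 is imposed by substituting the last component into
the normal equations; uncertainties come from multinomial bootstrap of
every population's counts, with an analytic GLS covariance available as a
cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

_COND_LIMIT = 1e10


@dataclass
class AdmixtureResult:
    """Mixing proportions with uncertainties and fit diagnostics."""

    m: np.ndarray
    SE: Optional[np.ndarray]
    residual: float  # weighted residual sum of squares
    n_boot: int = 0
    method: str = "substitution"


def _frequencies(counts: Sequence[int]) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    n = c.sum()
    if n < 1:
        raise ValueError("population must have at least one observation")
    return c / n


def wls_admixture(
    hybrid: Sequence[int],
    parentals: Sequence[Sequence[int]],
    mode: str = "substitution",
    analytic_se: bool = False,
) -> AdmixtureResult:
    """Weighted least-squares admixture proportions.

    Categories are weighted by w_i = 1/(pbar_i (1 - pbar_i)) where pbar is
    the unweighted mean of the parental frequencies; categories fixed or
    absent in every parental (pbar in {0, 1}) carry no information and are
    dropped. ``mode="substitution"`` solves the constrained normal equations
    in closed form and clips/renormalizes any out-of-range component;
    ``mode="constrained"`` solves the box- and simplex-constrained quadratic
    program instead.
    """
    K = len(parentals)
    if K < 2:
        raise ValueError("need at least 2 parental populations")
    h = _frequencies(hybrid)
    P = np.column_stack([_frequencies(p) for p in parentals])
    if P.shape[0] != h.shape[0]:
        raise ValueError("hybrid and parentals must share a category universe")

    pbar = P.mean(axis=1)
    keep = (pbar > 0) & (pbar < 1)
    if keep.sum() < K:
        raise ValueError(
            f"only {int(keep.sum())} informative categories for {K} proportions"
        )
    h, P, pbar = h[keep], P[keep], pbar[keep]
    w = 1.0 / (pbar * (1.0 - pbar))
    W = np.diag(w)

    if mode == "substitution":
        # substitute m_K = 1 - sum_{k<K} m_k into the normal equations
        A = P[:, :-1] - P[:, -1:]
        b = h - P[:, -1]
        AtW = A.T * w
        M = AtW @ A
        if np.linalg.cond(M) > _COND_LIMIT:
            raise ValueError(
                "collinear parental populations: reduced normal matrix is singular"
            )
        x = np.linalg.solve(M, AtW @ b)
        m = np.append(x, 1.0 - x.sum())
        if (m < 0).any() or (m > 1).any():
            m = np.clip(m, 0.0, 1.0)
            if m.sum() == 0:
                raise ValueError("degenerate solution: all proportions clipped to 0")
            m = m / m.sum()
        cov = np.linalg.inv(M)
    elif mode == "constrained":
        from scipy.optimize import minimize

        def objective(m: np.ndarray) -> float:
            r = h - P @ m
            return float(r @ (w * r))

        res = minimize(
            objective,
            np.full(K, 1.0 / K),
            method="SLSQP",
            bounds=[(0.0, 1.0)] * K,
            constraints=[{"type": "eq", "fun": lambda m: m.sum() - 1.0}],
        )
        if not res.success:
            raise ValueError(f"constrained solve failed: {res.message}")
        m = res.x / res.x.sum()
        cov = None
    else:
        raise ValueError(f"unknown mode {mode!r}")

    r = h - P @ m
    residual = float(r @ (w * r))
    SE = None
    if analytic_se and cov is not None:
        # GLS covariance of the K-1 free components; the last is 1 - sum
        dof = max(len(h) - (K - 1), 1)
        scale = residual / dof
        var_free = np.diag(cov) * scale
        var_last = float(np.ones(K - 1) @ cov @ np.ones(K - 1)) * scale
        SE = np.sqrt(np.append(var_free, var_last))
    return AdmixtureResult(m=m, SE=SE, residual=residual, method=mode)


def bootstrap_admixture(
    hybrid: Sequence[int],
    parentals: Sequence[Sequence[int]],
    B: int = 1000,
    seed: Optional[int] = None,
    mode: str = "substitution",
) -> AdmixtureResult:
    """Bootstrap standard errors for the WLS proportions.

    The hybrid and each parental are resampled multinomially at their
    observed sample sizes; SE is the standard deviation of the proportion
    estimates over the ``B`` successful replicates.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    point = wls_admixture(hybrid, parentals, mode=mode)
    rng = np.random.default_rng(seed)
    hybrid = np.asarray(hybrid, dtype=int)
    parentals = [np.asarray(p, dtype=int) for p in parentals]
    n_h = int(hybrid.sum())
    n_p = [int(p.sum()) for p in parentals]
    estimates = []
    for _ in range(B):
        h_star = rng.multinomial(n_h, hybrid / n_h)
        p_star = [
            rng.multinomial(n, p / n) for n, p in zip(n_p, parentals)
        ]
        try:
            estimates.append(wls_admixture(h_star, p_star, mode=mode).m)
        except ValueError:
            continue  # degenerate resample; skip
    if len(estimates) < 2:
        raise ValueError("too few successful bootstrap replicates")
    est = np.asarray(estimates)
    return AdmixtureResult(
        m=point.m,
        SE=est.std(axis=0, ddof=1),
        residual=point.residual,
        n_boot=len(estimates),
        method=mode,
    )
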
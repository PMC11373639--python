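"""Crossover genotype-by-time interaction proportion (Ψ).

A pair of genotypes (i, i') shows a *crossover* between two time points
(j, j') when their ranking by breeding value strictly reverses:
``(u_ij - u_i'j) > 0`` and ``(u_ij' - u_i'j') < 0``, or vice versa.  Ψ is
the proportion of crossover pairs among all genotype pairs; ties in either
difference count as non-crossover (the defining inequalities are strict).

Two estimators are provided: Monte-Carlo sampling of genotype pairs
(100,000 iterations by convention) and exact enumeration over all C(n, 2)
unordered pairs, which serves as the oracle for the sampler.  For breeding
values that are bivariate normal across the two time points with
correlation ρ, the population value is the orthant probability
``arccos(ρ) / π``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CrossoverResult:
    time_pair: tuple[str, str]
    psi: float
    method: str                 # "monte_carlo" or "exact"
    n_iter: int = 0             # 0 for the exact method
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.psi <= 1.0):
            raise ValueError(f"psi must lie in [0, 1], got {self.psi}")


def _columns(blups: pd.DataFrame, time_i: str, time_j: str) -> tuple[np.ndarray, np.ndarray]:
    for t in (time_i, time_j):
        if t not in blups.columns:
            raise ValueError(f"time point {t!r} not in BLUP matrix columns {list(blups.columns)}")
    if len(blups) < 2:
        raise ValueError("need at least 2 genotypes to evaluate crossovers")
    return blups[time_i].to_numpy(dtype=float), blups[time_j].to_numpy(dtype=float)


def psi_exact(blups: pd.DataFrame, time_i: str, time_j: str) -> CrossoverResult:
    """Exact crossover proportion over all unordered genotype pairs."""
    u, v = _columns(blups, time_i, time_j)
    su = np.sign(u[:, None] - u[None, :])
    sv = np.sign(v[:, None] - v[None, :])
    cross = (su * sv) == -1          # strict sign flip; any tie gives 0
    iu = np.triu_indices(len(u), k=1)
    return CrossoverResult(
        time_pair=(time_i, time_j),
        psi=float(cross[iu].mean()),
        method="exact",
    )


def psi_monte_carlo(
    blups: pd.DataFrame,
    time_i: str,
    time_j: str,
    n_iter: int = 100_000,
    seed: int = 0,
) -> CrossoverResult:
    """Monte-Carlo crossover proportion from sampled genotype pairs.

    Pairs (a, b), a ≠ b, are drawn uniformly with replacement; the reported
    Ψ is the fraction of sampled pairs whose sign of difference strictly
    flips between the two time points.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    u, v = _columns(blups, time_i, time_j)
    n = len(u)
    rng = np.random.default_rng(seed)
    a = rng.integers(0, n, size=n_iter)
    b = rng.integers(0, n - 1, size=n_iter)
    b = b + (b >= a)                 # uniform over ordered pairs with a != b
    du = np.sign(u[a] - u[b])
    dv = np.sign(v[a] - v[b])
    psi = float(np.mean((du * dv) == -1))
    return CrossoverResult(
        time_pair=(time_i, time_j),
        psi=psi,
        method="monte_carlo",
        n_iter=int(n_iter),
        seed=int(seed),
    )
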
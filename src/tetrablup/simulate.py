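"""Synthetic tetraploid breeding population with a known genetic truth.

The generator emulates the design of a southern-highbush-blueberry-style
postharvest trial: several hundred advanced-selection genotypes phenotyped
once each, sparse across three harvest years; a small panel of check
genotypes repeated in every year to connect the years (augmented design);
four postharvest storage time points with an unstructured genetic
covariance whose correlations decay with time lag; correlated residuals
within a harvest; fixed year effects; and two technical repetitions that
are averaged before modelling.

The population carries the family relatedness typical of an
advanced-selection breeding program: a pool of unrelated founder parents is
drawn with Binomial(ploidy, p) dosages at independent markers, crosses
(families) are sampled from the pool, and each genotype is an offspring of
one cross with tetrasomic gamete segregation (each parental gamete carries
a Hypergeometric(ploidy, dosage, ploidy/2) dose, i.e. random bivalent
chromosome segregation).  This preserves the marginal Binomial(ploidy, p)
dosage variance while creating the full-sib/half-sib kinship that makes
variance components and genomic prediction informative; set
``n_families=None`` for an idealized unrelated population.

The genetic architecture is purely additive and by default fully polygenic:
every marker carries a time-point-specific effect drawn from a multivariate
normal whose correlation matrix equals the target genetic correlation
structure, so the breeding-value covariance between genotypes is exactly
proportional to the realized marker relationship matrix (the model GBLUP
assumes).  A sparse architecture is available via ``n_qtl``.  Per-time
genetic variances are rescaled so the realized heritability matches its
target.  The realized quantities (breeding values, covariances,
heritabilities) are reported alongside the data so estimation methods can
be benchmarked against the truth of the actual sample, not the asymptotic
targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_tables import DosageMatrix, PhenotypeTable, TIME_POINTS


def _lag_corr(T: int, by_lag: Sequence[float]) -> np.ndarray:
    C = np.eye(T)
    for lag in range(1, T):
        r = by_lag[lag - 1] if lag - 1 < len(by_lag) else (by_lag[-1] if by_lag else 0.0)
        for i in range(T - lag):
            C[i, i + lag] = C[i + lag, i] = r
    return C


@dataclass
class SimulationConfig:
    """Study-design and genetic-architecture parameters of the generator.

    Defaults mirror the emulated trial: 588 genotypes of which 16 are
    checks repeated across 3 years, tetraploid dosages at 2,000 markers,
    4 storage time points with per-time heritability 0.5 and genetic
    correlations 0.9 / 0.7 / 0.4 at lags 1 / 2 / 3, unit residual variances
    with mildly decaying residual correlations, and 2 technical reps.
    """

    n_genotypes: int = 588
    n_checks: int = 16
    n_years: int = 3
    n_markers: int = 2000
    ploidy: int = 4
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_parents: int = 30
    n_families: int | None = 343
    n_qtl: int | None = None
    time_points: tuple[str, ...] = TIME_POINTS
    h2: tuple[float, ...] = (0.5, 0.5, 0.5, 0.5)
    genetic_corr_by_lag: tuple[float, ...] = (0.9, 0.7, 0.4)
    genetic_corr: np.ndarray | None = None
    residual_sd: tuple[float, ...] | None = None
    residual_corr_by_lag: tuple[float, ...] = (0.3, 0.2, 0.1)
    residual_corr: np.ndarray | None = None
    time_means: tuple[float, ...] | None = None
    year_effect_sd: float = 0.3
    n_reps: int = 2
    rep_noise_frac: float = 0.1
    trait: str = "trait1"
    seed: int = 0

    def __post_init__(self) -> None:
        T = len(self.time_points)
        if self.n_checks >= self.n_genotypes:
            raise ValueError("n_checks must be smaller than n_genotypes")
        if len(self.h2) != T:
            raise ValueError(f"need {T} heritability targets, got {len(self.h2)}")
        if any(not (0.0 <= h < 1.0) for h in self.h2):
            raise ValueError("heritability targets must lie in [0, 1)")
        if not (0.0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.n_qtl is not None and self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        if self.n_families is not None and self.n_parents < 2:
            raise ValueError("need at least 2 parents to make crosses")

    # -- derived matrices --------------------------------------------------

    @property
    def T(self) -> int:
        return len(self.time_points)

    def genetic_correlation_matrix(self) -> np.ndarray:
        C = (
            np.asarray(self.genetic_corr, dtype=float)
            if self.genetic_corr is not None
            else _lag_corr(self.T, self.genetic_corr_by_lag)
        )
        _check_corr(C, self.T, "genetic")
        return C

    def residual_covariance_matrix(self) -> np.ndarray:
        sd = np.asarray(self.residual_sd if self.residual_sd is not None else [1.0] * self.T)
        C = (
            np.asarray(self.residual_corr, dtype=float)
            if self.residual_corr is not None
            else _lag_corr(self.T, self.residual_corr_by_lag)
        )
        _check_corr(C, self.T, "residual")
        return C * np.outer(sd, sd)

    def time_mean_vector(self) -> np.ndarray:
        if self.time_means is not None:
            if len(self.time_means) != self.T:
                raise ValueError("time_means length mismatch")
            return np.asarray(self.time_means, dtype=float)
        # gentle postharvest decline on an arbitrary trait scale
        return 10.0 - 0.5 * np.arange(self.T)


def _check_corr(C: np.ndarray, T: int, label: str) -> None:
    if C.shape != (T, T):
        raise ValueError(f"{label} correlation matrix must be {T}x{T}")
    if not np.allclose(C, C.T):
        raise ValueError(f"{label} correlation matrix must be symmetric")
    if np.linalg.eigvalsh(C).min() < -1e-10:
        raise ValueError(f"{label} correlation matrix is not PSD")


@dataclass
class SyntheticTruth:
    """Ground truth realized by one simulated sample."""

    qtl_marker_ids: list[str]
    marker_effects: pd.DataFrame          # QTL x time
    breeding_values: pd.DataFrame         # genotype x time (all genotypes, checks included)
    sigma_t: pd.DataFrame                 # realized genetic covariance across times
    sigma_e: pd.DataFrame                 # residual covariance used by the generator
    h2: pd.Series                         # realized narrow-sense heritability per time
    year_effects: dict[int, float]
    config: SimulationConfig = field(repr=False)


def simulate_dosages(config: SimulationConfig) -> DosageMatrix:
    """Draw a genotypes × markers tetraploid dosage matrix.

    Marker j has allele frequency ``p_j ~ Uniform(maf_range)``.  With
    ``n_families=None`` every genotype is an i.i.d. ``Binomial(ploidy,
    p_j)`` draw — unlinked markers in polysomic Hardy-Weinberg equilibrium.
    Otherwise a founder pool of ``n_parents`` such draws is crossed into
    ``n_families`` biparental families and each genotype is one offspring:
    the sum of two tetrasomic gametes, each Hypergeometric(ploidy, parental
    dosage, ploidy/2).  Marginal dosage mean and variance are unchanged,
    but full-sib and half-sib kinship appears in the realized G.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 11]))
    p = rng.uniform(*config.maf_range, size=config.n_markers)
    shape = (config.n_genotypes, config.n_markers)
    if config.n_families is None:
        dos = rng.binomial(config.ploidy, p, size=shape)
    else:
        half = config.ploidy // 2
        parents = rng.binomial(config.ploidy, p, size=(config.n_parents, config.n_markers))
        crosses = np.empty((config.n_families, 2), dtype=int)
        for f in range(config.n_families):
            crosses[f] = rng.choice(config.n_parents, size=2, replace=False)
        fam = rng.integers(config.n_families, size=config.n_genotypes)
        d1 = parents[crosses[fam, 0]]
        d2 = parents[crosses[fam, 1]]
        g1 = rng.hypergeometric(d1, config.ploidy - d1, half)
        g2 = rng.hypergeometric(d2, config.ploidy - d2, half)
        dos = g1 + g2
    width = max(4, len(str(config.n_genotypes)))
    gids = [f"G{i:0{width}d}" for i in range(1, config.n_genotypes + 1)]
    mids = [f"M{j:05d}" for j in range(1, config.n_markers + 1)]
    return DosageMatrix(gids, mids, dos.astype(float), ploidy=config.ploidy)


def simulate_phenotypes(
    dosages: DosageMatrix, config: SimulationConfig
) -> tuple[PhenotypeTable, SyntheticTruth]:
    """Generate longitudinal phenotypes with known breeding values.

    Breeding value of genotype i at time t is ``sum_j w_ij a_jt`` over the
    QTL subset, with effect vectors ``a_j.`` drawn MVN(0, target genetic
    correlation) and each time column rescaled so the realized genetic
    variance hits the target implied by h2 and the residual variance.
    Phenotype = time mean + year effect + breeding value + within-harvest
    residual (MVN(0, Se)) + small technical-rep noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 23]))
    T = config.T
    Se = config.residual_covariance_matrix()
    Cg = config.genetic_correlation_matrix()
    mu = config.time_mean_vector()

    W = dosages.dosages - dosages.dosages.mean(axis=0)
    n_qtl = config.n_qtl if config.n_qtl is not None else config.n_markers
    qtl_idx = np.sort(rng.choice(config.n_markers, size=n_qtl, replace=False))
    alpha = rng.standard_normal((n_qtl, T)) @ np.linalg.cholesky(Cg).T
    bv = W[:, qtl_idx] @ alpha
    bv = bv - bv.mean(axis=0)

    sigma_e_diag = np.diag(Se)
    h2 = np.asarray(config.h2, dtype=float)
    target_var = h2 / (1.0 - h2) * sigma_e_diag
    realized = bv.var(axis=0, ddof=1)
    if (realized <= 0).any():
        raise ValueError("degenerate genetic variance in simulation; increase n_qtl")
    scale = np.sqrt(target_var / realized)
    bv = bv * scale
    alpha = alpha * scale

    gids = list(dosages.genotype_ids)
    n = len(gids)
    checks = gids[: config.n_checks]
    years = list(range(2021, 2021 + config.n_years))
    year_eff = rng.normal(0.0, config.year_effect_sd, size=config.n_years)
    assign = rng.integers(config.n_years, size=n)  # year of each non-check genotype

    Le = np.linalg.cholesky(Se + 1e-12 * np.eye(T))
    rep_sd = config.rep_noise_frac * np.sqrt(sigma_e_diag)

    rows = []
    resid_var_accum = []
    for i, g in enumerate(gids):
        is_check = g in set(checks)
        g_years = years if is_check else [years[assign[i]]]
        for yr in g_years:
            resid = Le @ rng.standard_normal(T)
            resid_var_accum.append(resid)
            base = mu + year_eff[years.index(yr)] + bv[i] + resid
            for t_i, tp in enumerate(config.time_points):
                for rep in range(1, config.n_reps + 1):
                    noise = rng.normal(0.0, rep_sd[t_i]) if config.n_reps > 1 else 0.0
                    rows.append((g, yr, tp, config.trait, base[t_i] + noise, is_check, rep))

    df = pd.DataFrame(rows, columns=["genotype", "year", "time_point", "trait",
                                     "value", "is_check", "rep"])
    table = PhenotypeTable(df, strict=True)

    times = list(config.time_points)
    resid_mat = np.asarray(resid_var_accum)
    realized_resid_var = resid_mat.var(axis=0, ddof=1)
    bv_var = bv.var(axis=0, ddof=1)
    truth = SyntheticTruth(
        qtl_marker_ids=[dosages.marker_ids[j] for j in qtl_idx],
        marker_effects=pd.DataFrame(
            alpha, index=[dosages.marker_ids[j] for j in qtl_idx], columns=times
        ),
        breeding_values=pd.DataFrame(bv, index=gids, columns=times),
        sigma_t=pd.DataFrame(np.cov(bv.T, ddof=1).reshape(T, T), index=times, columns=times),
        sigma_e=pd.DataFrame(Se, index=times, columns=times),
        h2=pd.Series(bv_var / (bv_var + realized_resid_var), index=times),
        year_effects=dict(zip(years, year_eff.tolist())),
        config=config,
    )
    return table, truth


def drop_time_points(table: PhenotypeTable, trait: str, keep_times: Sequence[str]) -> PhenotypeTable:
    """Restrict one trait to a subset of time points (single-time traits such
    as water loss at 7W or scar size at 1D), leaving other traits untouched."""
    df = table.df
    drop = (df["trait"] == trait) & ~df["time_point"].isin(list(keep_times))
    return PhenotypeTable(df[~drop], strict=False)
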
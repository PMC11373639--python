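"""Genetic and descriptive summaries of longitudinal fits and phenotypes.

Produces the quantities a breeding report tabulates: narrow-sense
heritability per storage time point, genetic correlations between time
points, phenotypic (Pearson) correlations between traits, baseline
regressions (how much of a later time point the harvest value explains),
and postharvest descriptive statistics (population means and the share of
genotypes that softened / firmed relative to harvest).
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import PhenotypeTable, TIME_POINTS
from .lmm import CovarianceComponents
from .traits import average_reps


def heritability(components: CovarianceComponents) -> pd.Series:
    """Narrow-sense heritability per time point.

    ``h2_i = sigma_g2(i) / (sigma_g2(i) + sigma_e2(i))`` from the diagonal
    genetic and residual variances of a longitudinal fit.
    """
    vg = np.diag(components.sigma_t.to_numpy())
    ve = np.diag(components.sigma_e.to_numpy())
    tot = vg + ve
    if (tot <= 0).any():
        bad = [t for t, s in zip(components.times, tot) if s <= 0]
        raise ValueError(f"zero total variance at time points {bad}; heritability undefined")
    return pd.Series(vg / tot, index=components.times, name="h2")


def genetic_correlations(components: CovarianceComponents) -> pd.DataFrame:
    """Genetic covariance rescaled to unit diagonal.

    Time points with (numerically) zero genetic variance get NaN rows and
    columns: a correlation with a degenerate margin is undefined.
    """
    S = components.sigma_t.to_numpy().copy()
    sd = np.sqrt(np.clip(np.diag(S), 0.0, None))
    zero = sd <= 1e-8 * max(sd.max(), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = S / np.outer(sd, sd)
    C[zero, :] = np.nan
    C[:, zero] = np.nan
    np.fill_diagonal(C, np.where(zero, np.nan, 1.0))
    if zero.any():
        warnings.warn(
            f"zero genetic variance at {list(np.array(components.times)[zero])}; "
            "correlations reported as missing"
        )
    return pd.DataFrame(np.clip(C, -1.0, 1.0), index=components.times, columns=components.times)


def _genotype_values(
    table: PhenotypeTable, trait: str, time_point: str, adjust_year: bool
) -> pd.Series:
    """Rep-averaged (optionally year-centred) value per genotype."""
    df = average_reps(table.filter(trait=trait, time_points=[time_point])).df
    df = df.dropna(subset=["value"])
    if adjust_year:
        df["value"] = df["value"] - df.groupby("year")["value"].transform("mean")
    return df.groupby("genotype")["value"].mean()


def phenotypic_correlation(
    table: PhenotypeTable,
    trait_a: str,
    trait_b: str,
    time_a: str,
    time_b: str,
    adjust_year: bool = True,
) -> float:
    """Pearson correlation across genotypes between two trait/time values.

    Values are rep-averaged and, by default, year-centred before pairing,
    because genotypes were phenotyped in different years; pass
    ``adjust_year=False`` for raw phenotypic values.
    """
    a = _genotype_values(table, trait_a, time_a, adjust_year)
    b = _genotype_values(table, trait_b, time_b, adjust_year)
    pair = pd.concat([a, b], axis=1, join="inner").dropna()
    if len(pair) < 3:
        raise ValueError(f"need >=3 genotypes with both values, got {len(pair)}")
    return float(stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])[0])


def baseline_regression_r2(
    table: PhenotypeTable,
    trait: str,
    baseline_time: str,
    target_time: str,
    adjust_year: bool = True,
) -> float:
    """R² of OLS regression of a later time point on the baseline value.

    Answers "how much of the trait at ``target_time`` does the value at
    harvest explain"; identical to the squared Pearson correlation of the
    same genotype pairs.
    """
    x = _genotype_values(table, trait, baseline_time, adjust_year)
    y = _genotype_values(table, trait, target_time, adjust_year)
    pair = pd.concat([x, y], axis=1, join="inner").dropna()
    if len(pair) < 3:
        raise ValueError(f"need >=3 genotypes with both values, got {len(pair)}")
    if np.isclose(pair.iloc[:, 0].std(ddof=0), 0.0):
        raise ValueError("baseline values are constant; regression undefined")
    res = stats.linregress(pair.iloc[:, 0], pair.iloc[:, 1])
    return float(res.rvalue**2)


def postharvest_descriptives(
    table: PhenotypeTable,
    trait: str,
    baseline_time: str = "1D",
    change_threshold: float | None = None,
    adjust_year: bool = False,
) -> pd.DataFrame:
    """Per-time-point population summaries and changes versus the baseline.

    For each time point: mean, min, max, and n.  For each non-baseline time
    point, paired within (genotype, year): the mean change from the
    baseline, the proportions of genotypes that decreased / increased /
    stayed exactly equal (strict inequalities; exact ties count as
    unchanged), and — when ``change_threshold`` is given — the proportion
    with ``|change| > change_threshold``.

    Raw rep-averaged values are summarized by default so means stay in trait
    units; set ``adjust_year=True`` for year-centred summaries.
    """
    df = average_reps(table.filter(trait=trait)).df.dropna(subset=["value"])
    if df["time_point"].nunique() < 2:
        raise ValueError(f"trait {trait!r} observed at fewer than 2 time points")
    if adjust_year:
        df["value"] = df["value"] - df.groupby(["year", "time_point"], observed=True)[
            "value"
        ].transform("mean")

    times = [t for t in TIME_POINTS if t in set(df["time_point"].astype(str))]
    wide = df.pivot_table(
        index=["genotype", "year"], columns="time_point", values="value", observed=True
    )

    rows = []
    for t in times:
        col = wide[t].dropna()
        row = {
            "time_point": t,
            "n": int(col.size),
            "mean": float(col.mean()),
            "min": float(col.min()),
            "max": float(col.max()),
        }
        if t != baseline_time and baseline_time in wide.columns:
            pair = wide[[baseline_time, t]].dropna()
            change = pair[t] - pair[baseline_time]
            n = len(change)
            if n:
                row.update(
                    mean_change=float(change.mean()),
                    prop_decreased=float((change < 0).sum() / n),
                    prop_increased=float((change > 0).sum() / n),
                    prop_unchanged=float((change == 0).sum() / n),
                )
                if change_threshold is not None:
                    row["prop_beyond_threshold"] = float(
                        (change.abs() > change_threshold).sum() / n
                    )
        rows.append(row)
    return pd.DataFrame(rows).set_index("time_point")


def summary_table(
    fits: Mapping[str, "object"],
    lrt: Mapping[str, tuple[float, float]] | None = None,
    psi: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Assemble a per-trait genetic-parameter table (h2 per time, LRT p, Ψ)."""
    rows = {}
    for trait, fit in fits.items():
        h2 = heritability(fit.components)
        row = {f"h2_{t}": h2[t] for t in h2.index}
        if lrt and trait in lrt:
            row["lrt_p"] = lrt[trait][1]
        if psi and trait in psi:
            row["psi"] = psi[trait]
        rows[trait] = row
    return pd.DataFrame(rows).T
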
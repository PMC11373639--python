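"""Shared fixtures: simulated populations at several scales.

The full-scale population (588 genotypes, 2,000 markers) is expensive to
fit repeatedly, so it and its longitudinal fit are session-scoped and
shared by the recovery, cross-validation, and summary tests.  The seed is
fixed once for the whole suite.
"""

import numpy as np
import pandas as pd
import pytest

from tetrablup import (
    ModelSpec,
    PhenotypeTable,
    SimulationConfig,
    fit_longitudinal,
    simulate_dosages,
    simulate_phenotypes,
    vanraden_grm,
)

#: master seed of the full-scale study fixture
STUDY_SEED = 20240725


@pytest.fixture(scope="session")
def default_population():
    cfg = SimulationConfig(seed=STUDY_SEED)
    dosages = simulate_dosages(cfg)
    pheno, truth = simulate_phenotypes(dosages, cfg)
    grm = vanraden_grm(dosages)
    return {"config": cfg, "dosages": dosages, "pheno": pheno, "truth": truth, "grm": grm}


@pytest.fixture(scope="session")
def default_fit(default_population):
    return fit_longitudinal(
        default_population["pheno"],
        default_population["grm"],
        ModelSpec(trait="trait1"),
    )


@pytest.fixture(scope="session")
def small_population():
    """150-genotype population for cheap model-level tests."""
    cfg = SimulationConfig(
        seed=11, n_genotypes=150, n_checks=8, n_markers=500,
        n_families=90, n_parents=15,
    )
    dosages = simulate_dosages(cfg)
    pheno, truth = simulate_phenotypes(dosages, cfg)
    grm = vanraden_grm(dosages)
    return {"config": cfg, "dosages": dosages, "pheno": pheno, "truth": truth, "grm": grm}


@pytest.fixture(scope="session")
def small_fit(small_population):
    return fit_longitudinal(
        small_population["pheno"], small_population["grm"], ModelSpec(trait="trait1")
    )


def balanced_table(y, genotype_ids, times, trait="tr", year=2021):
    """One-year, no-check phenotype table from a genotype x time value matrix."""
    rows = [
        (g, year, t, trait, y[i, ti], False, 1)
        for i, g in enumerate(genotype_ids)
        for ti, t in enumerate(times)
    ]
    df = pd.DataFrame(
        rows,
        columns=["genotype", "year", "time_point", "trait", "value", "is_check", "rep"],
    )
    return PhenotypeTable(df)


def tiny_instance(seed, n_genotypes=8, times=("1D", "1W"), drop_record=False):
    """A tiny fit problem with its simulation truth, for oracle comparisons."""
    T = len(times)
    cfg = SimulationConfig(
        seed=seed,
        n_genotypes=n_genotypes,
        n_checks=0,
        n_years=1,
        n_markers=80,
        n_families=None,
        time_points=times,
        h2=tuple([0.45] * T),
        genetic_corr_by_lag=(0.6, 0.4, 0.2)[: T - 1],
        residual_corr_by_lag=(0.2, 0.1, 0.05)[: T - 1],
        n_reps=1,
        year_effect_sd=0.0,
    )
    dosages = simulate_dosages(cfg)
    pheno, truth = simulate_phenotypes(dosages, cfg)
    grm = vanraden_grm(dosages, ridge=1e-6)
    if drop_record:
        df = pheno.df.drop(index=pheno.df.index[len(pheno.df) // 2])
        pheno = PhenotypeTable(df, strict=False)
    return pheno, grm, truth
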
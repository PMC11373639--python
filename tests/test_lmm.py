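"""Longitudinal REML engine: oracle agreement, invariants, tests on fits."""

import numpy as np
import pandas as pd
import pytest

from conftest import balanced_table, tiny_instance
from oracles import brute_force_reml, design_arrays

from tetrablup import (
    CovarianceComponents,
    GenomicRelationship,
    ModelSpec,
    PhenotypeTable,
    SimulationConfig,
    bic,
    fit_longitudinal,
    heritability,
    lrt_interaction,
    predict_gebv,
    simulate_dosages,
    simulate_phenotypes,
    solve_gblup,
    wald_time_effect,
)
from tetrablup.lmm import LongitudinalFit

TIMES2 = ("1D", "1W")


def _fit_tiny(pheno, grm, **kw):
    return fit_longitudinal(pheno, grm, ModelSpec(trait="trait1", time_points=TIMES2), **kw)


class TestRemlOracle:
    @pytest.mark.parametrize("seed,drop", [(301, False), (302, True), (303, False)])
    def test_matches_brute_force_maximization(self, seed, drop):
        """The REML optimum equals an independent derivative-free search."""
        pheno, grm, _ = tiny_instance(seed, drop_record=drop)
        fit = _fit_tiny(pheno, grm)
        y, X, G, gidx, tidx, uidx = design_arrays(pheno, grm, "trait1", TIMES2)
        ll_oracle = brute_force_reml(y, X, G, gidx, tidx, uidx, 2)
        assert fit.loglik == pytest.approx(ll_oracle, abs=1e-4)

    def test_balanced_and_general_routes_agree(self):
        pheno, grm, _ = tiny_instance(310, n_genotypes=10)
        fb = _fit_tiny(pheno, grm, engine="balanced")
        fg = _fit_tiny(pheno, grm, engine="general")
        assert fb.loglik == pytest.approx(fg.loglik, abs=1e-6)
        # routes are optimized independently, so estimates agree only to the
        # optimizer's resolution, not machine precision
        np.testing.assert_allclose(fb.blups.values, fg.blups.values, atol=1e-4)

    def test_unstructured_dominates_independent(self, small_population):
        """Nested models: the richer covariance cannot fit worse."""
        us = fit_longitudinal(small_population["pheno"], small_population["grm"],
                              ModelSpec(trait="trait1"))
        ind = fit_longitudinal(
            small_population["pheno"], small_population["grm"],
            ModelSpec(trait="trait1", genetic_structure="independent",
                      residual_structure="independent"))
        assert us.loglik >= ind.loglik - 1e-6


class TestFitBehaviour:
    def test_pure_noise_gives_boundary_genetic_variance(self):
        """With zero simulated heritability the genetic variances collapse.

        Boundary REML estimates carry half-normal sampling spread at n=200,
        so the assertion bounds were sized from that spread (checked across
        seeds), not from an idealized zero.
        """
        cfg = SimulationConfig(seed=77, n_genotypes=200, n_checks=8, n_markers=600,
                               n_families=60, n_parents=10,
                               time_points=("1D", "7W"), h2=(0.0, 0.0),
                               genetic_corr_by_lag=(0.6,), residual_corr_by_lag=(0.2,))
        dos = simulate_dosages(cfg)
        pheno, _ = simulate_phenotypes(dos, cfg)
        from tetrablup import vanraden_grm
        fit = fit_longitudinal(pheno, vanraden_grm(dos),
                               ModelSpec(trait="trait1", time_points=("1D", "7W")))
        vg = np.diag(fit.components.sigma_t.to_numpy())
        ve = np.diag(fit.components.sigma_e.to_numpy())
        assert (vg < 0.3 * ve).all()
        assert (vg / ve).mean() < 0.15

    def test_components_are_psd_and_h2_in_unit_interval(self, small_fit):
        for mat in (fit_mat.to_numpy() for fit_mat in
                    (small_fit.components.sigma_t, small_fit.components.sigma_e)):
            assert np.linalg.eigvalsh(mat).min() >= -1e-8
        h2 = heritability(small_fit.components)
        assert ((h2 >= 0) & (h2 <= 1)).all()

    def test_nonconvergence_is_flagged(self):
        pheno, grm, _ = tiny_instance(311)
        fit = _fit_tiny(pheno, grm, max_iter=1)
        assert not fit.converged
        assert fit.n_iter <= 1

    def test_univariate_special_case(self, small_population):
        """A single-time-point trait fits with a 1x1 covariance."""
        fit = fit_longitudinal(small_population["pheno"], small_population["grm"],
                               ModelSpec(trait="trait1", time_points=("7W",)))
        assert fit.components.sigma_t.shape == (1, 1)
        assert fit.n_params == 2
        assert 0.0 <= heritability(fit.components).iloc[0] <= 1.0


@pytest.fixture(scope="module")
def holdout_fit():
    cfg = SimulationConfig(seed=21, n_genotypes=60, n_checks=0, n_years=1,
                           n_markers=300, n_families=30, n_parents=10,
                           time_points=TIMES2, h2=(0.5, 0.5),
                           genetic_corr_by_lag=(0.7,), residual_corr_by_lag=(0.2,),
                           n_reps=1)
    dos = simulate_dosages(cfg)
    pheno, _ = simulate_phenotypes(dos, cfg)
    from tetrablup import vanraden_grm
    grm = vanraden_grm(dos)
    held = set(grm.genotype_ids[-10:])
    obs = PhenotypeTable(pheno.df[~pheno.df["genotype"].isin(held)], strict=False)
    fit = fit_longitudinal(obs, grm, ModelSpec(trait="trait1", time_points=TIMES2))
    return fit, grm, sorted(held)


class TestPredictGebv:

    def test_unphenotyped_genotypes_use_relationship_projection(self, holdout_fit):
        """u_new = G_new,obs G_obs^-1 u_obs for genotypes with no records."""
        fit, grm, held = holdout_fit
        obs = fit._obs_genotypes
        G_oo = grm.submatrix(obs)
        G_no = grm.cross(held, obs)
        expected = G_no @ np.linalg.solve(G_oo, fit.blups.loc[obs].values)
        np.testing.assert_allclose(fit.blups.loc[held].values, expected, atol=1e-8)

    def test_duplicated_relationship_row_shares_gebv(self, holdout_fit):
        fit, grm, _ = holdout_fit
        donor = fit._obs_genotypes[0]
        n = len(grm.genotype_ids)
        V = np.zeros((n + 1, n + 1))
        V[:n, :n] = grm.values
        di = grm.indices([donor])[0]
        V[n, :n] = grm.values[di, :]
        V[:n, n] = grm.values[:, di]
        V[n, n] = grm.values[di, di]
        g2 = GenomicRelationship(grm.genotype_ids + ["clone"], V, grm.ploidy, 0)
        fit._grm = g2
        try:
            pred = predict_gebv(fit, ["clone", donor])
        finally:
            fit._grm = grm
        np.testing.assert_allclose(pred.loc["clone"].values, pred.loc[donor].values,
                                   atol=1e-8)

    def test_unrelated_genotype_predicts_prior_mean_zero(self, holdout_fit):
        fit, grm, _ = holdout_fit
        n = len(grm.genotype_ids)
        V = np.zeros((n + 1, n + 1))
        V[:n, :n] = grm.values
        V[n, n] = 1.0
        g2 = GenomicRelationship(grm.genotype_ids + ["alien"], V, grm.ploidy, 0)
        fit._grm = g2
        try:
            pred = predict_gebv(fit, ["alien"])
        finally:
            fit._grm = grm
        np.testing.assert_allclose(pred.values, 0.0, atol=1e-10)

    def test_unknown_genotype_errors(self, holdout_fit):
        fit, _, _ = holdout_fit
        with pytest.raises(ValueError, match="nope"):
            predict_gebv(fit, ["nope"])


class TestWald:
    def test_large_time_effect_is_detected(self, small_fit):
        # the generator's postharvest decline is an enormous effect at n=150
        stat, p = wald_time_effect(small_fit)
        assert p < 1e-6

    def test_invariant_to_genotype_relabeling(self):
        pheno, grm, _ = tiny_instance(320, n_genotypes=10)
        stat1, _ = wald_time_effect(_fit_tiny(pheno, grm))
        mapping = {g: f"perm_{i}" for i, g in enumerate(reversed(grm.genotype_ids))}
        df = pheno.df.assign(genotype=pheno.df["genotype"].map(mapping))
        grm2 = GenomicRelationship([mapping[g] for g in grm.genotype_ids],
                                   grm.values, grm.ploidy, grm.n_markers_used)
        stat2, _ = wald_time_effect(fit_longitudinal(
            PhenotypeTable(df, strict=False), grm2,
            ModelSpec(trait="trait1", time_points=TIMES2)))
        assert stat1 == pytest.approx(stat2, rel=1e-6)

    def test_single_time_point_errors(self, small_population):
        fit = fit_longitudinal(small_population["pheno"], small_population["grm"],
                               ModelSpec(trait="trait1", time_points=("1D",)))
        with pytest.raises(ValueError):
            wald_time_effect(fit)

    def test_type_one_error_is_calibrated(self):
        """Equal time means: rejection rate near the nominal 5% level.

        The Wald test plugs in estimated variance components, so calibration
        is asymptotic; n=150 genotypes is large enough for the nominal level
        within Monte-Carlo error.
        """
        rng = np.random.default_rng(99)
        n = 150
        cfg = SimulationConfig(seed=1, n_genotypes=n, n_checks=0, n_years=1,
                               n_markers=400, n_families=None, time_points=TIMES2,
                               h2=(0.4, 0.4), genetic_corr_by_lag=(0.6,),
                               residual_corr_by_lag=(0.2,), n_reps=1,
                               time_means=(10.0, 10.0), year_effect_sd=0.0)
        dos = simulate_dosages(cfg)
        from tetrablup import vanraden_grm
        grm = vanraden_grm(dos)
        gids = list(grm.genotype_ids)
        rejections = 0
        n_rep = 100
        Le = np.linalg.cholesky(cfg.residual_covariance_matrix())
        for _ in range(n_rep):
            y = 10.0 + rng.standard_normal((n, 2)) @ Le.T  # no genetic, equal means
            tab = balanced_table(y, gids, TIMES2, trait="trait1")
            _, p = wald_time_effect(_fit_tiny(tab, grm))
            rejections += p < 0.05
        rate = rejections / n_rep
        assert 0.0 <= rate <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / n_rep)


class TestLrtAndBic:
    def test_equal_likelihoods_give_zero_statistic(self, small_fit):
        reduced = LongitudinalFit(
            spec=ModelSpec(trait="trait1", genetic_structure="common"),
            beta=small_fit.beta, blups=small_fit.blups,
            components=small_fit.components, loglik=small_fit.loglik,
            n_records=small_fit.n_records, n_params=small_fit.n_params - 9,
            converged=True, n_iter=1, times=small_fit.times,
            beta_cov=small_fit.beta_cov)
        stat, p = lrt_interaction(small_fit, reduced)
        assert stat == 0.0
        assert p == 1.0

    def test_non_nested_specs_rejected(self, small_fit):
        with pytest.raises(ValueError):
            lrt_interaction(small_fit, small_fit)

    def test_interaction_power_under_low_genetic_correlation(self):
        """Crossover-prone truth (r_g = 0.3) is flagged by the LRT."""
        hits = 0
        for seed in range(5):
            cfg = SimulationConfig(seed=400 + seed, n_genotypes=150, n_checks=6,
                                   n_markers=500, n_families=90, n_parents=12,
                                   time_points=TIMES2, h2=(0.5, 0.5),
                                   genetic_corr_by_lag=(0.3,),
                                   residual_corr_by_lag=(0.2,))
            dos = simulate_dosages(cfg)
            pheno, _ = simulate_phenotypes(dos, cfg)
            from tetrablup import vanraden_grm
            grm = vanraden_grm(dos)
            full = _fit_tiny(pheno, grm)
            reduced = fit_longitudinal(
                pheno, grm, ModelSpec(trait="trait1", time_points=TIMES2,
                                      genetic_structure="common"))
            _, p = lrt_interaction(full, reduced)
            hits += p < 0.05
        assert hits >= 4

    def test_bic_formula(self):
        fit = LongitudinalFit(
            spec=ModelSpec(trait="x"), beta=pd.Series(dtype=float),
            blups=pd.DataFrame(),
            components=CovarianceComponents(
                sigma_t=pd.DataFrame(np.eye(2)), sigma_e=pd.DataFrame(np.eye(2))),
            loglik=-100.0, n_records=100, n_params=3, converged=True, n_iter=5,
            times=TIMES2, beta_cov=np.eye(1))
        assert bic(fit) == pytest.approx(200 + 3 * np.log(100), abs=1e-3)


class TestCheckEffects:
    def test_check_contrasts_ignore_noncheck_subset(self):
        """Differences between check effects come from check data alone."""
        cfg = SimulationConfig(seed=31, n_genotypes=40, n_checks=4, n_years=2,
                               n_markers=200, n_families=None, time_points=TIMES2,
                               h2=(0.4, 0.4), genetic_corr_by_lag=(0.6,),
                               residual_corr_by_lag=(0.2,), n_reps=1)
        dos = simulate_dosages(cfg)
        pheno, _ = simulate_phenotypes(dos, cfg)
        from tetrablup import vanraden_grm
        grm = vanraden_grm(dos)
        spec = ModelSpec(trait="trait1", time_points=TIMES2)
        full = fit_longitudinal(pheno, grm, spec)
        # drop half the non-check genotypes, re-solve at the same components
        checks = set(pheno.check_genotypes)
        noncheck = [g for g in grm.genotype_ids if g not in checks]
        keep = checks | set(noncheck[: len(noncheck) // 2])
        sub = PhenotypeTable(pheno.df[pheno.df["genotype"].isin(keep)], strict=False)
        sol_full = solve_gblup(pheno, grm, spec, full.components)
        sol_sub = solve_gblup(sub, grm, spec, full.components)
        cols = [c for c in sol_full.beta.index if c.startswith("check:")]
        contrast_full = sol_full.beta[cols[1]] - sol_full.beta[cols[0]]
        contrast_sub = sol_sub.beta[cols[1]] - sol_sub.beta[cols[0]]
        assert contrast_full == pytest.approx(contrast_sub, abs=1e-6)
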
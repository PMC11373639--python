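"""Genetic and descriptive summaries."""

import numpy as np
import pandas as pd
import pytest

from tetrablup import (
    CovarianceComponents,
    PhenotypeTable,
    baseline_regression_r2,
    genetic_correlations,
    heritability,
    phenotypic_correlation,
    postharvest_descriptives,
)


def _components(sigma_t, sigma_e, times=("1D", "1W")):
    times = list(times)
    return CovarianceComponents(
        sigma_t=pd.DataFrame(sigma_t, index=times, columns=times),
        sigma_e=pd.DataFrame(sigma_e, index=times, columns=times),
    )


def _table(rows):
    return PhenotypeTable(pd.DataFrame(
        rows,
        columns=["genotype", "year", "time_point", "trait", "value", "is_check", "rep"],
    ), strict=False)


class TestHeritability:
    def test_variance_ratio(self):
        comp = _components(np.diag([2.0, 0.0]), np.diag([2.0, 1.0]))
        h2 = heritability(comp)
        assert h2["1D"] == pytest.approx(0.5)
        assert h2["1W"] == pytest.approx(0.0)

    def test_zero_total_variance_is_an_error(self):
        comp = _components(np.zeros((2, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="total variance"):
            heritability(comp)


class TestGeneticCorrelations:
    def test_diagonal_gives_identity(self):
        comp = _components(np.diag([1.0, 4.0]), np.eye(2))
        np.testing.assert_allclose(genetic_correlations(comp).values, np.eye(2))

    def test_off_diagonal_rescaled(self):
        comp = _components([[1.0, 0.9], [0.9, 1.0]], np.eye(2))
        assert genetic_correlations(comp).iloc[0, 1] == pytest.approx(0.9)

    def test_zero_variance_reported_missing(self):
        comp = _components([[1.0, 0.0], [0.0, 0.0]], np.eye(2))
        with pytest.warns(UserWarning, match="zero genetic variance"):
            corr = genetic_correlations(comp)
        assert np.isnan(corr.loc["1W"]).all()
        assert corr.loc["1D", "1D"] == 1.0

    def test_recovered_correlations_near_simulated_truth(self, small_fit,
                                                         small_population):
        est = genetic_correlations(small_fit.components).to_numpy()
        tc = small_population["truth"].sigma_t.to_numpy()
        sd = np.sqrt(np.diag(tc))
        realized = tc / np.outer(sd, sd)
        iu = np.triu_indices(4, 1)
        # n=150 genotypes: coarse agreement is all that is identifiable
        assert np.abs(est[iu] - realized[iu]).mean() < 0.25


class TestPhenotypicAssociation:
    @pytest.fixture(scope="class")
    def assoc_table(self):
        rng = np.random.default_rng(12)
        rows = []
        base = rng.normal(10, 2, 40)
        for i in range(40):
            rows.append((f"g{i}", 2021, "1D", "A", base[i], False, 1))
            rows.append((f"g{i}", 2021, "1D", "B", -base[i], False, 1))
            rows.append((f"g{i}", 2021, "7W", "A", 2 * base[i] + 5, False, 1))
            rows.append((f"g{i}", 2021, "7W", "C", rng.normal(), False, 1))
        return _table(rows)

    def test_trait_against_itself(self, assoc_table):
        assert phenotypic_correlation(assoc_table, "A", "A", "1D", "1D") == pytest.approx(1.0)

    def test_antisymmetric_values(self, assoc_table):
        assert phenotypic_correlation(assoc_table, "A", "B", "1D", "1D") == pytest.approx(-1.0)

    def test_too_few_pairs_rejected(self):
        table = _table([("g1", 2021, "1D", "A", 1.0, False, 1),
                        ("g1", 2021, "7W", "A", 2.0, False, 1),
                        ("g2", 2021, "1D", "A", 3.0, False, 1),
                        ("g2", 2021, "7W", "A", 1.0, False, 1)])
        with pytest.raises(ValueError, match=">=3"):
            phenotypic_correlation(table, "A", "A", "1D", "7W")

    def test_r2_of_exact_linear_relation_is_one(self, assoc_table):
        assert baseline_regression_r2(assoc_table, "A", "1D", "7W") == pytest.approx(1.0)

    def test_r2_equals_squared_correlation(self, assoc_table):
        r = phenotypic_correlation(assoc_table, "A", "C", "1D", "7W")
        r2 = baseline_regression_r2(assoc_table, "A", "1D", "7W")
        # same identity on the same pairs, different traits at the two times
        rows = assoc_table.df
        a = rows[(rows.trait == "A") & (rows.time_point == "1D")].set_index("genotype").value
        c = rows[(rows.trait == "C") & (rows.time_point == "7W")].set_index("genotype").value
        from scipy.stats import linregress
        assert linregress(a, c.loc[a.index]).rvalue ** 2 == pytest.approx(r ** 2)

    def test_independent_values_have_negligible_r2(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(1000):
            rows.append((f"g{i}", 2021, "1D", "A", rng.normal(), False, 1))
            rows.append((f"g{i}", 2021, "7W", "A", rng.normal(), False, 1))
        assert baseline_regression_r2(_table(rows), "A", "1D", "7W") < 0.01

    def test_constant_baseline_is_an_error(self):
        rows = [(f"g{i}", 2021, t, "A", 1.0 if t == "1D" else float(i), False, 1)
                for i in range(5) for t in ("1D", "7W")]
        with pytest.raises(ValueError, match="constant"):
            baseline_regression_r2(_table(rows), "A", "1D", "7W", adjust_year=False)


class TestDescriptives:
    def test_constant_trait(self):
        rows = [(f"g{i}", 2021, t, "A", 7.0, False, 1)
                for i in range(4) for t in ("1D", "7W")]
        out = postharvest_descriptives(_table(rows), "A")
        assert out.loc["7W", "mean_change"] == 0.0
        assert out.loc["7W", "prop_decreased"] == 0.0
        assert out.loc["7W", "prop_increased"] == 0.0
        assert out.loc["7W", "prop_unchanged"] == 1.0

    def test_known_changes(self):
        deltas = {"g0": 1.0, "g1": 2.0, "g2": -1.0, "g3": -2.0}
        rows = []
        for g, d in deltas.items():
            rows.append((g, 2021, "1D", "A", 10.0, False, 1))
            rows.append((g, 2021, "7W", "A", 10.0 + d, False, 1))
        out = postharvest_descriptives(_table(rows), "A", change_threshold=1.5)
        assert out.loc["7W", "mean_change"] == pytest.approx(0.0)
        assert out.loc["7W", "prop_decreased"] == pytest.approx(0.5)
        assert out.loc["7W", "prop_increased"] == pytest.approx(0.5)
        assert out.loc["7W", "prop_beyond_threshold"] == pytest.approx(0.5)

    def test_proportions_partition_unity(self, small_population):
        out = postharvest_descriptives(small_population["pheno"], "trait1")
        for t in ("1W", "3W", "7W"):
            total = (out.loc[t, "prop_decreased"] + out.loc[t, "prop_increased"]
                     + out.loc[t, "prop_unchanged"])
            assert total == pytest.approx(1.0)

    def test_single_time_trait_rejected(self):
        rows = [(f"g{i}", 2021, "1D", "A", float(i), False, 1) for i in range(4)]
        with pytest.raises(ValueError, match="fewer than 2"):
            postharvest_descriptives(_table(rows), "A")
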
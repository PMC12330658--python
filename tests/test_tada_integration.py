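"""Family de novo Bayes factors, BF combination, Bayesian FDR, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist, poisson

from tadard import (DeNovoBFParams, FDRConfig, bayesian_fdr, combine_bfs,
                    denovo_bayes_factor, integrate_evidence, select_genes)


class TestDeNovoBayesFactor:
    def test_zero_count_favors_null(self):
        params = DeNovoBFParams(n_trios=5000, gamma_mean=20)
        assert denovo_bayes_factor(0, 2e-6, params) < 1

    def test_nearly_point_mass_relative_risk_is_neutral(self):
        # beta -> infinity concentrates the Gamma prior at gamma_mean; with
        # gamma_mean -> 1 the alternative collapses onto the null
        params = DeNovoBFParams(n_trios=5000, gamma_mean=1.0 + 1e-9,
                                beta=1e7)
        for x in (0, 1, 3):
            assert denovo_bayes_factor(x, 5e-6, params) == pytest.approx(
                1.0, rel=1e-3)

    def test_closed_form_matches_quadrature(self):
        params = DeNovoBFParams(n_trios=5000, gamma_mean=20, beta=1.0)
        a, b = params.gamma_mean * params.beta, params.beta
        for x, mu in [(0, 2e-6), (1, 1e-5), (3, 5e-6), (2, 2e-7)]:
            lam0 = 2 * params.n_trios * mu
            marginal = quad(lambda g: poisson.pmf(x, lam0 * g)
                            * gamma_dist.pdf(g, a, scale=1 / b), 0, 300)[0]
            oracle = marginal / poisson.pmf(x, lam0)
            assert denovo_bayes_factor(x, mu, params) == pytest.approx(
                oracle, rel=1e-3)

    def test_non_decreasing_in_count(self):
        params = DeNovoBFParams(n_trios=5000)
        bfs = denovo_bayes_factor(np.arange(6), 3e-6, params)
        assert (np.diff(bfs) > 0).all()

    def test_invalid_inputs_rejected(self):
        params = DeNovoBFParams(n_trios=5000)
        with pytest.raises(ValueError):
            denovo_bayes_factor(-1, 1e-6, params)
        with pytest.raises(ValueError):
            denovo_bayes_factor(1, 0.0, params)
        with pytest.raises(ValueError):
            DeNovoBFParams(n_trios=0)


class TestCombineBFs:
    @pytest.mark.parametrize("fam,rd,expected", [
        (0.5, 2.0, 2.0),   # weak family evidence floored, not penalising
        (3.0, 4.0, 12.0),
        (0.2, 0.3, 1.0),   # both floored
    ])
    def test_flooring_identities(self, fam, rd, expected):
        assert combine_bfs(fam, rd) == expected

    def test_exhaustive_small_grid(self):
        vals = np.array([0.1, 0.5, 1.0, 2.0, 50.0])
        for f in vals:
            for r in vals:
                assert combine_bfs(f, r) == max(f, 1) * max(r, 1)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            combine_bfs(0.0, 2.0)

    @given(f=st.floats(1e-6, 1e6), r=st.floats(1e-6, 1e6),
           f2=st.floats(1e-6, 1e6))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_and_floored(self, f, r, f2):
        out = combine_bfs(f, r)
        assert out >= 1.0
        if f2 >= f:
            assert combine_bfs(f2, r) >= out


class TestBayesianFDR:
    def test_single_gene_balance_point(self):
        # BF = (1-pi)/pi makes the posterior exactly 1/2
        pi = 0.06
        table = pd.DataFrame({"gene_id": ["g"], "bf_final": [(1 - pi) / pi]})
        out = bayesian_fdr(table, FDRConfig(pi_risk=pi))
        assert out.loc[0, "posterior_p1"] == pytest.approx(0.5)
        assert out.loc[0, "qvalue"] == pytest.approx(0.5)

    def test_huge_bf_vanishing_q(self):
        table = pd.DataFrame({"gene_id": ["g"], "bf_final": [1e12]})
        assert bayesian_fdr(table).loc[0, "qvalue"] < 1e-9

    def test_three_gene_hand_computation(self):
        table = pd.DataFrame({"gene_id": ["a", "b", "c"],
                              "bf_final": [100.0, 10.0, 1.0]})
        out = bayesian_fdr(table, FDRConfig(pi_risk=0.06))
        # frozen cumulative means of 1 - posterior, computed by hand:
        # 0.94/6.94, then +0.94/1.54, then +0.94
        np.testing.assert_allclose(
            out["qvalue"], [0.13544669, 0.37291815, 0.56194543], atol=1e-7)

    def test_q_monotone_along_ranking(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({"gene_id": [f"g{i}" for i in range(200)],
                              "bf_final": rng.lognormal(0, 2, 200)})
        out = bayesian_fdr(table)
        assert (np.diff(out["qvalue"]) >= -1e-15).all()
        assert out["qvalue"].between(0, 1).all()
        assert out.loc[0, "qvalue"] == pytest.approx(
            1 - out.loc[0, "posterior_p1"])

    def test_empty_table(self):
        out = bayesian_fdr(pd.DataFrame(columns=["gene_id", "bf_final"]))
        assert len(out) == 0


class TestSelection:
    def test_no_selection_when_q_is_one(self):
        table = pd.DataFrame({"gene_id": ["a", "b"], "bf_final": [1e-6, 1e-6]})
        out = select_genes(bayesian_fdr(table))
        assert not out["selected_fdr"].any()
        assert not out["selected_bonferroni"].any()

    def test_small_q_selected(self):
        table = pd.DataFrame({"gene_id": ["a"], "bf_final": [1e6]})
        out = select_genes(bayesian_fdr(table))
        assert out.loc[0, "selected_fdr"]

    def test_bonferroni_subset_of_fdr(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame({"gene_id": [f"g{i}" for i in range(500)],
                              "bf_final": rng.lognormal(0, 3, 500)})
        out = select_genes(bayesian_fdr(table))
        assert (out["selected_bonferroni"] <= out["selected_fdr"]).all()


class TestIntegration:
    def test_neutral_rd_reproduces_family_only_ranking(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(80)]
        family = pd.DataFrame({"gene_id": genes,
                               "bf_family": rng.lognormal(0, 2, 80)})
        rd_neutral = pd.DataFrame({"gene_id": genes, "bf_rd": 1.0})
        merged = integrate_evidence(family, rd_neutral)
        family_only = bayesian_fdr(
            family.assign(bf_final=np.maximum(family["bf_family"], 1.0)))
        assert list(merged["gene_id"]) == list(family_only["gene_id"])
        np.testing.assert_allclose(merged["qvalue"], family_only["qvalue"])

    def test_missing_stream_treated_as_neutral(self):
        family = pd.DataFrame({"gene_id": ["a", "b"], "bf_family": [5.0, 2.0]})
        rd = pd.DataFrame({"gene_id": ["b", "c"], "bf_rd": [3.0, 4.0]})
        out = integrate_evidence(family, rd).set_index("gene_id")
        assert out.loc["a", "bf_final"] == 5.0
        assert out.loc["b", "bf_final"] == 6.0
        assert out.loc["c", "bf_final"] == 4.0

    def test_family_counts_converted_with_params(self):
        family = pd.DataFrame({"gene_id": ["a"], "x": [2], "mu": [2e-6]})
        rd = pd.DataFrame({"gene_id": ["a"], "bf_rd": [1.0]})
        params = DeNovoBFParams(n_trios=5000)
        out = integrate_evidence(family, rd, denovo_params=params)
        expected = max(denovo_bayes_factor(2, 2e-6, params), 1.0)
        assert out.loc[0, "bf_final"] == pytest.approx(expected)
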
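"""Cox fitting, cohort filtering, directional counting, and permutation nulls."""

import numpy as np
import pandas as pd
import pytest

import oracles
from tftargets.simulate import simulate_cohort
from tftargets.survival import (
    DEFAULT_EXCLUDED_HISTOLOGIES,
    DegenerateCovariateError,
    GeneSetSurvivalModel,
    filter_cohort,
    fit_cox_univariate,
    permutation_relative_se,
    preprocess_expression,
)


class TestPreprocess:
    @pytest.mark.parametrize("raw, expected", [(0, 0.0), (9, 1.0), (99, 2.0)])
    def test_log10_plus_one(self, raw, expected):
        assert preprocess_expression(raw) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            preprocess_expression(-1.0)


class TestFilterCohort:
    def _cohort(self, histologies):
        return pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(len(histologies))],
            "time": 1.0, "event": 1, "histology": histologies,
        })

    def test_neuroendocrine_removed_case_insensitively(self):
        df = self._cohort(["Neuroendocrine Carcinoma", "ductal adenocarcinoma",
                           "  neuroendocrine  ", "adenosquamous"])
        kept = filter_cohort(df)
        assert list(kept["sample_id"]) == ["S1", "S3"]

    def test_empty_exclusion_list_keeps_all(self):
        df = self._cohort(list(DEFAULT_EXCLUDED_HISTOLOGIES))
        assert len(filter_cohort(df, exclusion_labels=[])) == len(df)

    def test_mixed_cohort_matches_string_oracle(self):
        labels = ["ductal adenocarcinoma", "neuroendocrine", "NEUROENDOCRINE CARCINOMA NOS",
                  "colloid carcinoma", "neuroendocrine carcinoma", "acinar",
                  "Moderately differentiated ductal adenocarcinoma 60% + neuroendocrine 40%",
                  "ductal", "82463 neuroendocrine carcinoma nos", "mucinous"]
        df = self._cohort(labels)
        normalized = {" ".join(e.lower().split()) for e in DEFAULT_EXCLUDED_HISTOLOGIES}
        expected = [f"S{i}" for i, lbl in enumerate(labels)
                    if " ".join(lbl.lower().split()) not in normalized]
        assert list(filter_cohort(df)["sample_id"]) == expected


class TestCoxFit:
    def test_constant_covariate_raises(self):
        with pytest.raises(DegenerateCovariateError):
            fit_cox_univariate([1, 2, 3, 4], [1, 1, 0, 0], [2.0, 2.0, 2.0, 2.0])

    def test_four_subject_example_matches_grid_search(self):
        times, events, x = [1, 2, 3, 4], [1, 1, 0, 0], [1.0, 0.0, 1.0, 0.0]
        fit = fit_cox_univariate(times, events, x)
        oracle = oracles.cox_grid_maximizer(times, events, x)
        assert fit.beta == pytest.approx(oracle, abs=1e-3)

    def test_random_datasets_match_partial_likelihood_grid(self, rng):
        for _ in range(5):
            n = 30
            times = rng.exponential(1.0, n) + 0.01
            events = rng.integers(0, 2, n)
            if events.sum() < 2:
                events[:2] = 1
            times[rng.integers(0, n)] = times[0]  # force at least one tie
            x = rng.normal(0, 1, n)
            fit = fit_cox_univariate(times, events, x)
            if abs(fit.beta) < 4.5:  # inside the oracle's grid
                oracle = oracles.cox_grid_maximizer(times, events, x)
                assert fit.beta == pytest.approx(oracle, abs=1e-3)

    def test_matches_lifelines_with_ties(self, rng):
        """Independent cross-check of beta, se and p against lifelines."""
        from lifelines import CoxPHFitter

        n = 120
        times = np.round(rng.exponential(5.0, n), 1) + 0.1  # rounding creates ties
        events = (rng.random(n) < 0.7).astype(int)
        x = rng.normal(0, 1, n)
        fit = fit_cox_univariate(times, events, x)
        cph = CoxPHFitter()
        cph.fit(pd.DataFrame({"T": times, "E": events, "x": x}),
                duration_col="T", event_col="E")
        assert fit.beta == pytest.approx(cph.params_["x"], abs=1e-5)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], rel=1e-4)
        assert fit.wald_p == pytest.approx(
            cph.summary.loc["x", "p"], rel=1e-3)

    def test_breslow_ties_match_grid_oracle(self, rng):
        n = 80
        times = np.round(rng.exponential(5.0, n), 0) + 1
        events = (rng.random(n) < 0.8).astype(int)
        x = rng.normal(0, 1, n)
        fit = fit_cox_univariate(times, events, x, ties="breslow")
        oracle = oracles.cox_grid_maximizer(times, events, x, ties="breslow")
        assert fit.beta == pytest.approx(oracle, abs=1e-3)

    def test_monotone_likelihood_flagged_not_crashed(self):
        # perfectly separating covariate: events only at high x
        times = [1, 2, 3, 4, 5, 6]
        events = [1, 1, 0, 0, 0, 0]
        x = [10.0, 9.0, 1.0, 0.5, 0.2, 0.1]
        fit = fit_cox_univariate(times, events, x)
        assert not fit.converged
        assert abs(fit.beta) <= 20.0


class TestGeneSetModel:
    def _model(self, n=150, betas=None, seed=7):
        genes = [f"g{i}" for i in range(12)]
        expr, clin, _ = simulate_cohort(
            n_samples=n, genes=genes, hazard_genes=betas or {},
            excluded_fraction=0.1, seed=seed,
        )
        return GeneSetSurvivalModel(expr, clin), genes

    def test_excluded_histologies_dropped_before_fitting(self):
        model, _ = self._model(n=100)
        assert len(model.times) < 100

    def test_single_gene_fdr_equals_wald_p(self):
        model, genes = self._model()
        res = model.fit([genes[0]])
        assert res.table["fdr_q"].iloc[0] == pytest.approx(res.table["wald_p"].iloc[0])

    def test_planted_gene_ranks_first_with_reduced_direction(self):
        model, genes = self._model(n=500, betas={"g3": 1.0})
        res = model.fit(genes)
        assert res.table.index[0] == "g3"
        assert res.table.loc["g3", "direction"] == "reduced"
        count, frac = res.count_significant(0.25, "reduced")
        assert count >= 1

    def test_count_significant_directions_partition(self):
        model, genes = self._model(n=300, betas={"g1": 0.8, "g2": -0.8})
        res = model.fit(genes)
        n_red, _ = res.count_significant(0.25, "reduced")
        n_inc, _ = res.count_significant(0.25, "increased")
        total = int((res.table["fdr_q"] < 0.25).sum())
        assert n_red + n_inc == total

    def test_gene_order_invariance(self):
        model, genes = self._model(n=200, betas={"g5": 0.9})
        a = model.fit(genes).table
        b = model.fit(list(reversed(genes))).table
        pd.testing.assert_frame_equal(a, b)

    def test_summary_mentions_counts(self):
        model, genes = self._model()
        text = model.fit(genes).summary()
        assert "genes fitted: 12" in text and "FDR<0.1" in text


class TestPermutationTest:
    def test_zero_observed_gives_p_one(self):
        genes = [f"g{i}" for i in range(30)]
        expr, clin, _ = simulate_cohort(n_samples=60, genes=genes, seed=2)
        model = GeneSetSurvivalModel(expr, clin)
        res = model.fit(genes[:5])
        if res.count_significant(0.1)[0] == 0:
            perm = res.permutation_test(genes, N=200, threshold=0.1, seed=0)
            assert perm.empirical_p == pytest.approx(1.0)

    def test_seed_reproducibility_and_cache_consistency(self):
        genes = [f"g{i}" for i in range(25)]
        expr, clin, _ = simulate_cohort(n_samples=80, genes=genes,
                                        hazard_genes={"g0": 1.2}, seed=5)
        model = GeneSetSurvivalModel(expr, clin)
        res = model.fit(genes[:6])
        a = res.permutation_test(genes, N=300, threshold=0.25, seed=42)
        # second call reuses the warm cache; a fresh model has a cold cache
        b = res.permutation_test(genes, N=300, threshold=0.25, seed=42)
        fresh = GeneSetSurvivalModel(expr, clin).fit(genes[:6]).permutation_test(
            genes, N=300, threshold=0.25, seed=42)
        assert np.array_equal(a.null_fractions, b.null_fractions)
        assert np.array_equal(a.null_fractions, fresh.null_fractions)
        assert a.empirical_p == fresh.empirical_p

    def test_relative_se_values(self):
        assert permutation_relative_se(0.5, 2) == pytest.approx(np.sqrt(0.5))
        assert permutation_relative_se(0.05, 10_000) < 0.10
        one = permutation_relative_se(0.2, 1_000)
        two = permutation_relative_se(0.2, 2_000)
        assert one / two == pytest.approx(np.sqrt(2))
        with pytest.raises(ValueError):
            permutation_relative_se(0.0, 100)
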
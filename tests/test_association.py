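"""Association stage: correlations, polynomial OLS with degree selection,
Cox windows, pairwise models with VIF, and interaction tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dietfrail.association import (
    FrailtyModel,
    MortalityModel,
    interaction_tests,
    pairwise_score_models,
    score_correlations,
    standardized_beta,
)
from dietfrail.errors import DomainError, ValidationError


def _toy(n=2000, seed=0, beta=0.02, quad=0.0, sigma=0.01):
    rng = np.random.default_rng(seed)
    score = rng.normal(5.0, 1.5, n)
    sc = score - score.mean()
    frailty = 0.10 + beta * sc + quad * sc**2 + rng.normal(0, sigma, n)
    return pd.DataFrame(
        {
            "score": score,
            "frailty_index": frailty,
            "age": rng.uniform(20, 85, n),
            "sex": rng.choice(["male", "female"], n),
        }
    )


class TestCorrelations:
    def test_self_and_sign_flips(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": -x})
        corr = score_correlations(df)
        assert corr.loc["a", "a"] == pytest.approx(1.0)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_five_point_toy_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 4.0, 4.5, 7.0])
        y = np.array([0.3, 0.1, 0.5, 0.9, 0.6])
        # explicit product-moment formula as the independent oracle
        r_oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        corr = score_correlations(pd.DataFrame({"x": x, "y": y}))
        assert corr.loc["x", "y"] == pytest.approx(r_oracle, abs=1e-12)

    def test_weighted_matches_replication(self):
        """Integer weights equal replicating rows."""
        df = pd.DataFrame({"x": [1.0, 2.0, 5.0], "y": [2.0, 1.0, 4.0]})
        w = np.array([3.0, 1.0, 2.0])
        rep = df.loc[df.index.repeat(w.astype(int))]
        expected = score_correlations(rep).loc["x", "y"]
        got = score_correlations(df, weights=w).loc["x", "y"]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_flagged(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = score_correlations(df)
        assert np.isnan(corr.loc["x", "c"])


class TestStandardizedBeta:
    @pytest.mark.parametrize(
        "b,sx,sy,expected", [(0.0, 2.0, 1.0, 0.0), (0.008, 1.5, 0.10, 0.12), (0.7, 0.3, 0.3, 0.7)]
    )
    def test_values(self, b, sx, sy, expected):
        assert standardized_beta(b, sx, sy) == pytest.approx(expected)

    def test_zero_outcome_sd_rejected(self):
        with pytest.raises(DomainError):
            standardized_beta(1.0, 1.0, 0.0)


class TestFrailtyModel:
    def test_linear_recovery(self):
        df = _toy(n=5000, seed=3, beta=0.02)
        res = FrailtyModel(df, "score", covariates=["age", "sex"]).fit()
        assert res.selected_degree == 1
        row = res.params.loc["score"]
        assert row["ci_low"] <= 0.02 <= row["ci_high"]

    def test_quadratic_truth_selects_degree_two(self):
        hits = 0
        for seed in range(20):
            df = _toy(n=2000, seed=seed, beta=0.0, quad=0.004)
            res = FrailtyModel(df, "score", covariates=[]).fit()
            hits += res.selected_degree == 2
        assert hits >= 17

    def test_constant_exposure_rank_error(self):
        df = _toy(n=200, seed=1)
        df["score"] = 3.0
        with pytest.raises(ValidationError, match="score"):
            FrailtyModel(df, "score", covariates=["age"]).fit()

    def test_unit_scale_contract(self):
        """Rescaling the exposure rescales b by 1/c; p and the standardized
        beta are unchanged."""
        df = _toy(n=1500, seed=4)
        res1 = FrailtyModel(df, "score", covariates=["age"], unit_scale=1.0).fit()
        res10 = FrailtyModel(df, "score", covariates=["age"], unit_scale=10.0).fit()
        b1 = res1.params.loc["score"]
        b10 = res10.params.loc["score"]
        assert b10["coef"] == pytest.approx(10.0 * b1["coef"], rel=1e-8)
        assert b10["pvalue"] == pytest.approx(b1["pvalue"], abs=1e-8)
        assert b10["std_beta"] == pytest.approx(b1["std_beta"], rel=1e-8)

    def test_equal_weights_match_unweighted_estimates(self):
        df = _toy(n=1000, seed=5)
        res_u = FrailtyModel(df, "score", covariates=["age", "sex"]).fit()
        res_w = FrailtyModel(
            df, "score", covariates=["age", "sex"], weights=np.full(len(df), 2.5)
        ).fit()
        assert res_w.params.loc["score", "coef"] == pytest.approx(
            res_u.params.loc["score", "coef"], rel=1e-10
        )

    def test_mds_gets_energy_covariate(self, scored_cohort):
        model = FrailtyModel(scored_cohort, "mds")
        assert model.add_energy
        res = model.fit()
        assert "nut_energy_kcal" in res.sm_results.params.index
        # not when NI is adjusted for alongside
        model2 = FrailtyModel(scored_cohort, "mds", extra_covariates=["nutrition_index"])
        assert not model2.add_energy

    def test_deficit_scores_reported_per_tenth_point(self, scored_cohort):
        res = FrailtyModel(scored_cohort, "nutrition_index", degree_max=1).fit()
        assert res.model.unit_scales["nutrition_index"] == 0.1


class TestMortalityModel:
    def test_window_monotonicity(self, scored_cohort):
        r3 = MortalityModel(scored_cohort, "nutrition_index", window=3, degree_max=1).fit()
        r8 = MortalityModel(scored_cohort, "nutrition_index", window=8, degree_max=1).fit()
        assert r3.n_events <= r8.n_events

    def test_hr_direction_recovered(self, scored_cohort):
        # generated with HR 1.15 per 0.1 NI point
        res = MortalityModel(scored_cohort, "nutrition_index", covariates=[], degree_max=1).fit()
        hr = res.params.loc["nutrition_index", "hr"]
        assert 1.0 < hr < 1.4

    def test_all_censored_is_error(self, scored_cohort):
        df = scored_cohort.copy()
        df["event"] = 0
        with pytest.raises(DomainError, match="events"):
            MortalityModel(df, "nutrition_index", degree_max=1).fit()

    def test_equal_weights_match_unweighted_estimates(self, scored_cohort):
        res_u = MortalityModel(scored_cohort, "edii", covariates=["age"], degree_max=1).fit()
        res_w = MortalityModel(
            scored_cohort, "edii", covariates=["age"], degree_max=1,
            weights=np.full(len(scored_cohort), 3.0),
        ).fit()
        assert res_w.params.loc["edii", "coef"] == pytest.approx(
            res_u.params.loc["edii", "coef"], rel=1e-6
        )


class TestPairwise:
    def test_independent_scores_have_unit_vif(self):
        rng = np.random.default_rng(8)
        n = 3000
        df = pd.DataFrame(
            {
                "s1": rng.normal(size=n),
                "s2": rng.normal(size=n),
                "frailty_index": rng.normal(0.1, 0.05, n),
                "age": rng.uniform(20, 85, n),
            }
        )
        out = pairwise_score_models(df, "s1", "s2", covariates=["age"])
        assert out.vif["s1"] < 1.2 and out.warning is None
        assert {"s1", "s2"} <= set(out.results.params.index)

    def test_collinear_scores_trigger_vif_warning(self):
        rng = np.random.default_rng(9)
        n = 2000
        s1 = rng.normal(size=n)
        s2 = s1 + rng.normal(0, np.sqrt(1 / 0.99**2 - 1), n) * 0  # r ~ 1
        s2 = 0.99 * s1 + np.sqrt(1 - 0.99**2) * rng.normal(size=n)
        df = pd.DataFrame(
            {"s1": s1, "s2": s2, "frailty_index": rng.normal(0.1, 0.05, n), "age": rng.uniform(20, 85, n)}
        )
        with pytest.warns(UserWarning, match="VIF"):
            out = pairwise_score_models(df, "s1", "s2", covariates=["age"])
        assert out.vif["s1"] > 10

    def test_identical_scores_rejected(self, scored_cohort):
        with pytest.raises(DomainError):
            pairwise_score_models(scored_cohort, "mds", "mds")

    def test_ni_hei_pair_reports_both(self, scored_cohort):
        out = pairwise_score_models(
            scored_cohort, "nutrition_index", "hei2015", covariates=["age", "sex"], degree_max=1
        )
        assert {"nutrition_index", "hei2015"} <= set(out.results.params.index)


class TestInteractions:
    def test_empty_moderators_rejected(self, scored_cohort):
        with pytest.raises(DomainError):
            interaction_tests(scored_cohort, "mds", [], outcome="frailty")

    def test_null_interaction_pvalues_roughly_uniform(self):
        pvals = []
        for seed in range(200):
            df = _toy(n=400, seed=seed, beta=0.01)
            p = interaction_tests(df, "score", ["age", "sex"], covariates=["age", "sex"])
            pvals.append(next(iter(p.values())))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_strong_sex_interaction_detected(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            n = 10_000
            score = rng.normal(5, 1.5, n)
            female = rng.random(n) < 0.5
            frailty = 0.1 + 0.005 * score + 0.01 * score * female + rng.normal(0, 0.02, n)
            df = pd.DataFrame(
                {
                    "score": score,
                    "frailty_index": frailty,
                    "sex": np.where(female, "female", "male"),
                    "age": rng.uniform(20, 85, n),
                }
            )
            p = interaction_tests(df, "score", ["sex"], covariates=["age", "sex"])
            hits += next(iter(p.values())) < 0.05
        assert hits >= 4

    def test_mortality_four_way_term_named(self, scored_cohort):
        p = interaction_tests(
            scored_cohort, "edii", ["age", "sex", "frailty"], outcome="mortality"
        )
        (term, pval), = p.items()
        assert term == "edii*age*sex*frailty"
        assert 0.0 <= pval <= 1.0
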
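"""OLS fits, nested ANOVA, residual regression and the permutation null."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from pathburden.association import (
    CollinearityError,
    ModelError,
    fit_linear_model,
    nested_anova,
    random_pathway_null,
    residual_dose_regression,
    score_association,
)
from pathburden.scoring import PathwayScoreVector, pathway_am_score
from pathburden.synthetic import SimConfig

from conftest import BASE_COVARIATES, make_study
from _oracles import ols_normal_equations


def _vec(values, index, weighted=False):
    return PathwayScoreVector(
        pathway_name="p",
        scores=pd.Series(values, index=index, name="score"),
        weighted=weighted,
        n_variants=0,
    )


class TestFitLinearModel:
    def test_noiseless_linear_fit_is_exact(self):
        x = np.linspace(0, 10, 30)
        data = pd.DataFrame({"y": 2.0 + 3.0 * x, "x": x})
        fit = fit_linear_model(data, "y", ["x"])
        assert fit.params["x"] == pytest.approx(3.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)
        assert fit.r2 == pytest.approx(1.0)

    def test_duplicated_column_raises_naming_it(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        data = pd.DataFrame({"y": rng.normal(size=50), "x1": x, "x2": x})
        with pytest.raises(CollinearityError, match="x2"):
            fit_linear_model(data, "y", ["x1", "x2"])

    def test_complete_case_exclusion_counted(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(
            {"y": rng.normal(size=40), "x": rng.normal(size=40)}
        )
        data.loc[data.index[:3], "x"] = np.nan
        fit = fit_linear_model(data, "y", ["x"])
        assert fit.n_used == 37
        assert fit.n_excluded_missing == 3

    def test_coefficients_match_normal_equations_oracle(self):
        study = make_study(SimConfig(seed=17, n_samples=200))
        score = pathway_am_score(study.counts, study.pathway_variants)
        data = study.data.copy()
        data["score"] = score.scores
        covs = [*BASE_COVARIATES, "score"]
        fit = fit_linear_model(data, "dose", covs)
        x = np.column_stack(
            [np.ones(len(data)), *(data[c].to_numpy() for c in covs)]
        )
        beta = ols_normal_equations(x, data["dose"].to_numpy())
        assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)
        # and statsmodels agrees on the standard errors
        sm_fit = sm.OLS(data["dose"], sm.add_constant(data[covs])).fit()
        assert np.allclose(fit.bse.to_numpy(), sm_fit.bse.to_numpy(), rtol=1e-8)


class TestNestedAnova:
    def _fits(self, data, covs, term):
        base = fit_linear_model(data, "y", covs)
        full = fit_linear_model(data, "y", [*covs, term])
        return base, full

    def test_f_equals_squared_t_and_statsmodels(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(
            {
                "y": rng.normal(size=60),
                "x": rng.normal(size=60),
                "s": rng.normal(size=60),
            }
        )
        base, full = self._fits(data, ["x"], "s")
        res = nested_anova(base, full)
        sm_full = sm.OLS(data["y"], sm.add_constant(data[["x", "s"]])).fit()
        assert res.f_statistic == pytest.approx(
            float(sm_full.tvalues["s"]) ** 2, rel=1e-10
        )
        sm_base = sm.OLS(data["y"], sm.add_constant(data[["x"]])).fit()
        table = sm.stats.anova_lm(sm_base, sm_full)
        assert res.f_statistic == pytest.approx(table["F"].iloc[1], rel=1e-10)
        assert res.p_value == pytest.approx(table["Pr(>F)"].iloc[1], rel=1e-8)

    def test_perfect_full_fit_gives_zero_p(self):
        x = np.linspace(0, 1, 20)
        data = pd.DataFrame({"y": 1 + 2 * x, "x": np.random.default_rng(3).normal(size=20), "s": x})
        base, full = self._fits(data, ["x"], "s")
        res = nested_anova(base, full)
        # RSS_full is zero up to floating noise; p collapses accordingly
        assert res.p_value < 1e-100
        assert res.f_statistic > 1e20

    def test_orthogonal_term_f_near_zero(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=100)
        y = 1 + x + rng.normal(size=100)
        data = pd.DataFrame({"y": y, "x": x})
        # build a term exactly orthogonal to the base residuals and design
        base = fit_linear_model(data, "y", ["x"])
        z = rng.normal(size=100)
        xmat = np.column_stack([np.ones(100), x, y])
        z -= xmat @ np.linalg.lstsq(xmat, z, rcond=None)[0]
        data["s"] = z
        full = fit_linear_model(data, "y", ["x", "s"])
        res = nested_anova(base, full)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-8)
        assert res.p_value == pytest.approx(1.0, abs=1e-4)

    def test_mismatched_sample_sets_rejected(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame(
            {"y": rng.normal(size=30), "x": rng.normal(size=30), "s": rng.normal(size=30)}
        )
        base = fit_linear_model(data.iloc[:25], "y", ["x"])
        full = fit_linear_model(data, "y", ["x", "s"])
        with pytest.raises(ModelError, match="sample sets"):
            nested_anova(base, full)

    def test_nonnested_covariates_rejected(self):
        rng = np.random.default_rng(6)
        data = pd.DataFrame(
            {"y": rng.normal(size=30), "x": rng.normal(size=30), "s": rng.normal(size=30)}
        )
        base = fit_linear_model(data, "y", ["x"])
        full = fit_linear_model(data, "y", ["s"])
        with pytest.raises(ModelError, match="exactly one"):
            nested_anova(base, full)


class TestResidualDoseRegression:
    def test_perfect_prediction_zero_coefficient(self):
        rng = np.random.default_rng(7)
        idx = [f"S{i}" for i in range(50)]
        dose = pd.Series(rng.uniform(2, 10, 50), index=idx)
        score = _vec(rng.integers(0, 20, 50).astype(float), idx)
        res = residual_dose_regression(dose, dose.copy(), score)
        assert res.coefficient == pytest.approx(0.0, abs=1e-12)

    def test_recovers_constructed_slope(self):
        rng = np.random.default_rng(8)
        idx = [f"S{i}" for i in range(300)]
        score = _vec(rng.integers(5, 35, 300).astype(float), idx)
        predicted = pd.Series(rng.uniform(3, 8, 300), index=idx)
        dose = predicted + (-0.3) * score.scores + rng.normal(0, 0.8, 300)
        res = residual_dose_regression(dose, predicted, score)
        assert abs(res.coefficient - (-0.3)) <= 2 * res.std_error
        assert res.coefficient < 0

    def test_missing_predictions_excluded_and_counted(self):
        rng = np.random.default_rng(9)
        idx = [f"S{i}" for i in range(40)]
        dose = pd.Series(rng.uniform(2, 10, 40), index=idx)
        predicted = dose + rng.normal(0, 0.5, 40)
        predicted.iloc[:4] = np.nan
        score = _vec(rng.integers(0, 20, 40).astype(float), idx)
        res = residual_dose_regression(dose, predicted, score)
        assert res.n_used == 36
        assert res.n_excluded_missing == 4

    def test_constant_score_rejected(self):
        idx = [f"S{i}" for i in range(20)]
        dose = pd.Series(np.linspace(2, 8, 20), index=idx)
        score = _vec(np.full(20, 7.0), idx)
        with pytest.raises(ModelError, match="constant"):
            residual_dose_regression(dose, dose * 1.1, score)


@pytest.fixture(scope="module")
def null_study():
    return make_study(SimConfig(seed=19, n_samples=150, genes=12,
                                pathway_genes=5))


class TestRandomPathwayNull:
    @pytest.fixture()
    def study(self, null_study):
        return null_study

    def _observed(self, study):
        vec = pathway_am_score(study.counts, study.pathway_variants)
        return score_association(study.data, "dose", BASE_COVARIATES, vec)

    def test_seeded_determinism(self, study):
        obs = self._observed(study)
        kw = dict(B=25, size=5, seed=42)
        n1 = random_pathway_null(
            study.gene_variants, study.counts, study.data, "dose",
            BASE_COVARIATES, obs, **kw
        )
        n2 = random_pathway_null(
            study.gene_variants, study.counts, study.data, "dose",
            BASE_COVARIATES, obs, **kw
        )
        assert n1.null_statistics == n2.null_statistics
        assert n1.empirical_p == n2.empirical_p

    def test_add_one_rule_when_observed_beats_all(self, study):
        obs = self._observed(study)
        obs.p_value = 0.0  # more extreme than any null draw
        null = random_pathway_null(
            study.gene_variants, study.counts, study.data, "dose",
            BASE_COVARIATES, obs, B=100, size=5, seed=1
        )
        assert null.empirical_p == pytest.approx(1 / 101)

    def test_fast_path_matches_reference_association(self, study):
        """A forced draw of the observed gene set reproduces its p exactly."""
        obs = self._observed(study)
        null = random_pathway_null(
            study.gene_variants, study.counts, study.data, "dose",
            BASE_COVARIATES, obs, B=3, size=5, seed=1,
            gene_set_collection=[list(study.pathway.gene_ids)],
        )
        assert null.null_statistics == pytest.approx([obs.p_value] * 3, rel=1e-12)
        assert null.empirical_p == 1.0

    def test_invalid_b_rejected(self, study):
        obs = self._observed(study)
        with pytest.raises(ModelError):
            random_pathway_null(
                study.gene_variants, study.counts, study.data, "dose",
                BASE_COVARIATES, obs, B=0, size=5, seed=1
            )

    def test_abs_t_statistic_mode(self, study):
        obs = self._observed(study)
        null = random_pathway_null(
            study.gene_variants, study.counts, study.data, "dose",
            BASE_COVARIATES, obs, B=50, size=5, seed=9, statistic="abs_t"
        )
        assert null.statistic == "abs_t"
        assert all(s >= 0 for s in null.null_statistics)
        assert 0 < null.empirical_p <= 1
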
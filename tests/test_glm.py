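"""Tests for the CountGLM estimator: MLEs, inference, sklearn contract."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from sklearn.base import clone

from countreg import CountGLM
from countreg.distributions import FamilySpec, bell_mean_to_lambda
from countreg.glm import fit as fit_design, predict as predict_design
from countreg.synth import generate_monthly_design
from conftest import small_scenario

FAMILIES = ("poisson", "negbin", "pig", "bell")


@pytest.fixture(scope="module")
def nb_design():
    return generate_monthly_design(small_scenario(seed=21, n_months=150))


class TestClosedFormMLE:
    def test_poisson_intercept_only(self):
        m = CountGLM("poisson").fit(np.zeros((4, 0)), [2, 4, 3, 3])
        assert m.intercept_ == pytest.approx(np.log(3.0), abs=1e-8)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_intercept_only_fitted_mean_is_sample_mean(self, family, rng):
        # each family fitted to its own draws, so dispersion MLEs are interior
        from countreg.distributions import FamilySpec, family_rvs

        spec = FamilySpec(family, 0.5 if family in ("negbin", "pig") else None)
        y = family_rvs(spec, 5.0, (150,), rng)
        m = CountGLM(family).fit(np.zeros((150, 0)), y)
        assert m.fitted_means_[0] == pytest.approx(y.mean(), abs=1e-6)

    def test_bell_score_equation(self, rng):
        # lam*e^lam at the optimum equals the sample mean
        y = rng.poisson(4.0, 100)
        m = CountGLM("bell").fit(np.zeros((100, 0)), y)
        lam = float(bell_mean_to_lambda(m.fitted_means_[0]))
        assert lam * np.exp(lam) == pytest.approx(y.mean(), abs=1e-8)


class TestOracleAgreement:
    def test_poisson_matches_statsmodels(self, nb_design):
        m = fit_design("poisson", nb_design)
        X = sm.add_constant(nb_design.drop(columns=["month", "y"]).to_numpy())
        ref = sm.GLM(nb_design["y"].to_numpy(), X, family=sm.families.Poisson()).fit()
        assert np.abs(m.beta_ - ref.params).max() < 1e-5
        assert m.loglik_ == pytest.approx(ref.llf, abs=1e-4)
        assert np.abs(np.sqrt(np.diag(m.vcov_)) - ref.bse).max() < 1e-5

    def test_negbin_matches_statsmodels(self, nb_design):
        m = fit_design("negbin", nb_design)
        X = sm.add_constant(nb_design.drop(columns=["month", "y"]).to_numpy())
        ref = sm.NegativeBinomial(nb_design["y"].to_numpy(), X).fit(disp=0)
        assert np.abs(m.beta_ - ref.params[:-1]).max() < 1e-5
        assert m.dispersion_ == pytest.approx(ref.params[-1], abs=1e-4)
        assert m.loglik_ == pytest.approx(ref.llf, abs=1e-5)


class TestLikelihoodProperties:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_full_dominates_reduced(self, family, nb_design):
        full = fit_design(family, nb_design)
        reduced = fit_design(family, nb_design[["month", "y", "x_score"]])
        assert full.loglik_ >= reduced.loglik_ - 1e-6
        assert full.k_params_ > reduced.k_params_

    def test_negbin_nests_poisson(self, rng):
        y = rng.poisson(4.0, 200)
        X = rng.normal(size=(200, 1))
        m_nb = CountGLM("negbin").fit(X, y)
        m_p = CountGLM("poisson").fit(X, y)
        assert m_nb.dispersion_ < 1e-3  # boundary
        assert abs(m_nb.loglik_ - m_p.loglik_) < 1e-3

    @pytest.mark.parametrize("family", FAMILIES)
    def test_centering_equivariance(self, family, nb_design):
        m1 = fit_design(family, nb_design)
        shifted = nb_design.copy()
        shifted["x_score"] = shifted["x_score"] - shifted["x_score"].mean()
        m2 = fit_design(family, shifted)
        assert np.abs(m1.coef_ - m2.coef_).max() < 1e-6
        assert m1.intercept_ != pytest.approx(m2.intercept_, abs=1e-4)


class TestPredict:
    def test_training_prediction_equals_fitted(self, nb_design):
        m = fit_design("negbin", nb_design)
        np.testing.assert_allclose(predict_design(m, nb_design), m.fitted_means_)

    def test_link_algebra(self, nb_design):
        m = fit_design("poisson", nb_design)
        X = nb_design.drop(columns=["month", "y"])
        bumped = X.copy()
        bumped["x_lab"] += 1.0
        j = list(X.columns).index("x_lab")
        ratio = m.predict(bumped) / m.predict(X)
        np.testing.assert_allclose(ratio, np.exp(m.coef_[j]), rtol=1e-10)

    def test_intercept_only_predicts_constant(self):
        m = CountGLM("poisson").fit(np.zeros((5, 0)), [1, 2, 3, 2, 2])
        np.testing.assert_allclose(m.predict(np.zeros((3, 0))), np.exp(m.intercept_))

    def test_column_mismatch_raises(self, nb_design):
        m = fit_design("poisson", nb_design)
        bad = nb_design.drop(columns=["month", "y", "x_lab"])
        with pytest.raises(ValueError, match="x_lab"):
            m.predict(bad)


class TestInference:
    def test_coef_table_shape_and_pvalues(self, nb_design):
        tab = fit_design("negbin", nb_design).coef_table()
        assert list(tab["variable"]) == ["const", "x_share", "x_score", "x_lab"]
        assert ((tab["p_value"] >= 0) & (tab["p_value"] <= 1)).all()
        np.testing.assert_allclose(tab["z"], tab["coef"] / tab["se"])
        # the strong effect is detected, in this fixture
        assert tab.set_index("variable").loc["x_score", "p_value"] < 0.05

    def test_parameter_recovery_within_3se(self):
        # single seeded replicate per family; the replicated version is the
        # acceptance check
        truth = np.array([1.0, 1.2, 0.5, 0.0])
        for family in FAMILIES:
            fam = FamilySpec(family, 0.5 if family in ("negbin", "pig") else None)
            d = generate_monthly_design(small_scenario(family=fam, n_months=800, seed=31))
            m = fit_design(family, d)
            se = np.sqrt(np.diag(m.vcov_))
            assert np.all(np.abs(m.beta_ - truth) < 4 * se), family


class TestValidation:
    def test_rank_deficient_names_columns(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=50)})
        X["b"] = 2 * X["a"]
        with pytest.raises(ValueError, match="b"):
            CountGLM("poisson").fit(X, rng.poisson(2, 50))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="count"):
            CountGLM("poisson").fit(np.zeros((4, 1)), [-1, 2, 0, 1])

    def test_too_few_rows(self, rng):
        X = rng.normal(size=(3, 3))
        with pytest.raises(ValueError, match="observations"):
            CountGLM("poisson").fit(X, [1, 2, 1])

    def test_sklearn_contract(self, nb_design):
        m = CountGLM("pig", dispersion=0.3, max_iter=99)
        params = m.get_params()
        assert params["family"] == "pig" and params["max_iter"] == 99
        m2 = clone(m).set_params(family="negbin", dispersion=None)
        X = nb_design.drop(columns=["month", "y"])
        m2.fit(X, nb_design["y"])
        assert hasattr(m2, "beta_") and m2.dispersion_ is not None
        # RegressorMixin score is response-scale R^2
        assert m2.score(X, nb_design["y"]) <= 1.0
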
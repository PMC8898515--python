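"""Weighted logistic numerics, MI pooling, EM selection model, summaries."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit, logit

from conftest import make_mar_cohort, make_mcar_cohort, make_selection_cohort
from nrbias.missingness import (
    CollinearityError,
    MechanismTriplet,
    NoRespondersError,
    fit_em_nonignorable,
    fit_weighted_logistic,
    impute_mar,
    prevalence_mcar,
    prevalence_mnar,
    summarize_mechanisms,
    weighted_logistic_loglik,
)
from nrbias.published import MECHANISM_TRIPLETS


class TestWeightedLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], dtype=float)
        X = np.ones((10, 1))
        fit = fit_weighted_logistic(X, y)
        assert fit.params[0] == pytest.approx(logit(0.3), abs=1e-8)

    def test_halved_weight_duplicates_equal_unit_rows(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(40), rng.standard_normal(40)])
        y = (rng.random(40) < expit(X[:, 1])).astype(float)
        fit_unit = fit_weighted_logistic(X, y)
        X2 = np.vstack([X, X])
        y2 = np.concatenate([y, y])
        fit_half = fit_weighted_logistic(X2, y2, np.full(80, 0.5))
        np.testing.assert_allclose(fit_unit.params, fit_half.params, atol=1e-9)

    def test_matches_brute_force_likelihood_grid(self):
        """Two-stage dense grid over (b0, b1) on a small weighted
        instance: the IRLS optimum agrees with the grid argmax to 1e-4
        and its likelihood is never beaten."""
        rng = np.random.default_rng(1)
        n = 30
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = (rng.random(n) < expit(0.4 + 0.9 * X[:, 1])).astype(float)
        w = rng.uniform(0.2, 2.0, n)
        fit = fit_weighted_logistic(X, y, w)

        def grid_argmax(c0, c1, half, step):
            g0 = np.arange(c0 - half, c0 + half + step / 2, step)
            g1 = np.arange(c1 - half, c1 + half + step / 2, step)
            B = np.array([[b0, b1] for b0 in g0 for b1 in g1]).T  # (2, K)
            eta = X @ B  # (n, K)
            lls = (w * y) @ eta - w @ np.logaddexp(0.0, eta)
            k = int(np.argmax(lls))
            return B[:, k], float(lls[k])

        coarse, _ = grid_argmax(0.0, 0.0, 3.0, 0.01)
        fine, ll_fine = grid_argmax(coarse[0], coarse[1], 0.02, 1e-4)
        np.testing.assert_allclose(fit.params, fine, atol=1e-4 + 1e-9)
        assert weighted_logistic_loglik(fit.params, X, y, w) >= ll_fine - 1e-9

    def test_matches_statsmodels_glm(self):
        """Independent cross-check against a GLM fit with frequency
        weights."""
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        n = 200
        X = np.column_stack([np.ones(n), rng.standard_normal(n), rng.random(n)])
        y = (rng.random(n) < expit(X @ np.array([0.3, 1.0, -0.7]))).astype(float)
        w = rng.uniform(0.5, 1.5, n)
        fit = fit_weighted_logistic(X, y, w)
        glm = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit()
        np.testing.assert_allclose(fit.params, glm.params, atol=1e-6)

    def test_collinear_design_rejected(self):
        X = np.column_stack([np.ones(20), np.arange(20.0), 2 * np.arange(20.0)])
        y = (np.arange(20) % 2).astype(float)
        with pytest.raises(CollinearityError):
            fit_weighted_logistic(X, y)

    def test_separation_flagged_not_fatal(self):
        X = np.column_stack([np.ones(20), np.r_[np.zeros(10), np.ones(10)]])
        y = np.r_[np.zeros(10), np.ones(10)]
        with pytest.warns(RuntimeWarning, match="separation"):
            fit = fit_weighted_logistic(X, y)
        assert fit.separation


class TestPrevalenceMcar:
    def test_equals_complete_case_mean(self):
        responses = pd.DataFrame(
            {
                "subject_id": range(6),
                "returned": [1, 1, 1, 1, 0, 0],
                "y": [1, 0, 1, 1, np.nan, np.nan],
            }
        )
        assert prevalence_mcar(responses, "y") == pytest.approx(75.0)

    def test_all_ones(self):
        responses = pd.DataFrame(
            {"subject_id": [0, 1], "returned": [1, 1], "y": [1.0, 1.0]}
        )
        assert prevalence_mcar(responses, "y") == 100.0

    def test_no_responders_rejected(self):
        responses = pd.DataFrame(
            {"subject_id": [0], "returned": [0], "y": [np.nan]}
        )
        with pytest.raises(NoRespondersError):
            prevalence_mcar(responses, "y")


class TestImputeMar:
    def test_rubin_total_decomposition(self):
        frame, responses, y = make_mar_cohort(seed=0, n=4000)
        res = impute_mar(frame, responses, "y", ["x1", "x2", "x3"], m=25, seed=1)
        assert res.total == pytest.approx(
            res.within + (1 + 1 / 25) * res.between, abs=1e-10
        )
        assert res.pooled == pytest.approx(np.mean(res.estimates), abs=1e-10)

    def test_single_imputation_has_no_between_term(self):
        frame, responses, y = make_mar_cohort(seed=0, n=4000)
        res = impute_mar(frame, responses, "y", ["x1", "x2", "x3"], m=1, seed=1)
        assert res.between == 0.0
        assert res.total == pytest.approx(res.within)

    def test_mcar_data_reduces_to_complete_case(self):
        frame, responses, y = make_mcar_cohort(seed=3, n=20000)
        res = impute_mar(frame, responses, "y", ["x1", "x2", "x3"], m=25, seed=4)
        cc = prevalence_mcar(responses, "y")
        mc_se = 100.0 * np.sqrt(res.total)
        assert abs(res.pooled - cc) < 2 * mc_se + 0.3

    def test_mar_recovery_where_complete_case_fails(self):
        """Response depends on covariates predicting y upward: the
        complete-case mean overshoots, MI recovers the latent truth."""
        frame, responses, y = make_mar_cohort(seed=5)
        latent = 100.0 * y.mean()
        cc = prevalence_mcar(responses, "y")
        res = impute_mar(frame, responses, "y", ["x1", "x2", "x3"], m=25, seed=6)
        mc_se = 100.0 * np.sqrt(res.total)
        assert cc > latent + 5  # constructed upward bias
        assert abs(res.pooled - latent) < 2 * mc_se + 0.5

    def test_seeded_determinism(self):
        frame, responses, y = make_mar_cohort(seed=0, n=2000)
        a = impute_mar(frame, responses, "y", ["x1", "x2"], m=5, seed=9)
        b = impute_mar(frame, responses, "y", ["x1", "x2"], m=5, seed=9)
        assert a.estimates == b.estimates


class TestEMSelectionModel:
    def test_no_missing_data_is_a_fixed_point(self):
        """With full response the EM reduces to ordinary logistic fits and
        the MNAR prevalence equals the observed mean."""
        rng = np.random.default_rng(10)
        n = 2000
        x = rng.standard_normal(n)
        y = (rng.random(n) < expit(0.3 + x)).astype(float)
        frame = pd.DataFrame({"subject_id": range(n), "x": x})
        responses = pd.DataFrame(
            {"subject_id": range(n), "returned": 1, "y": y}
        )
        fit = fit_em_nonignorable(frame, responses, "y", ["x"])
        X = np.column_stack([np.ones(n), x])
        direct = fit_weighted_logistic(X, y)
        np.testing.assert_allclose(fit.beta.to_numpy(), direct.params, atol=1e-5)
        assert prevalence_mnar(fit, frame, responses, "y") == pytest.approx(
            100.0 * y.mean(), abs=1e-9
        )

    def test_monotone_ascent_and_convergence(self):
        frame, responses, y = make_selection_cohort(seed=0)
        fit = fit_em_nonignorable(frame, responses, "y", ["x1", "x2"])
        diffs = np.diff(fit.loglik)
        assert np.all(diffs >= -1e-10)
        assert fit.converged

    def test_posterior_weights_are_probabilities(self):
        frame, responses, y = make_selection_cohort(seed=1)
        fit = fit_em_nonignorable(frame, responses, "y", ["x1", "x2"])
        assert ((fit.weights >= 0) & (fit.weights <= 1)).all()
        assert len(fit.weights) == int((responses["returned"] == 0).sum())

    def test_parameter_recovery_on_selection_data(self):
        """Median estimates over selection-model replicates track the
        generating parameters (scaled-down version of the full study)."""
        truth = np.array([1.0, 2.5, -2.0, 1.0, 0.8, -0.8, -2.0])
        ests = []
        for s in range(20):
            frame, responses, y = make_selection_cohort(seed=s)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_em_nonignorable(frame, responses, "y", ["x1", "x2"])
            ests.append(
                np.r_[fit.beta.to_numpy(), fit.alpha.to_numpy(), fit.gamma]
            )
        med = np.median(ests, axis=0)
        rel = np.abs((med - truth) / truth)
        assert np.all(rel < 0.15)

    def test_mnar_recovers_where_complete_case_fails(self):
        """gamma < 0 masks y=1 subjects: the complete-case mean is far
        below the latent prevalence, the selection-model estimate is not."""
        gaps_cc = []
        gaps_mnar = []
        for s in range(5):
            frame, responses, y = make_selection_cohort(seed=100 + s, n=20000)
            latent = 100.0 * y.mean()
            cc = prevalence_mcar(responses, "y")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_em_nonignorable(frame, responses, "y", ["x1", "x2"])
            mnar = prevalence_mnar(fit, frame, responses, "y")
            gaps_cc.append(abs(cc - latent))
            gaps_mnar.append(abs(mnar - latent))
        assert np.median(gaps_cc) > 5.0
        assert np.median(gaps_mnar) < 2.0

    def test_marginal_variant_close_to_posterior_on_ignorable_data(self):
        frame, responses, y = make_mcar_cohort(seed=8, n=20000)
        fit = fit_em_nonignorable(frame, responses, "y", ["x1", "x2", "x3"])
        post = prevalence_mnar(fit, frame, responses, "y")
        marg = prevalence_mnar(fit, frame, responses, "y", method="marginal")
        assert abs(post - marg) < 1.0

    def test_no_responders_rejected(self):
        frame = pd.DataFrame({"subject_id": [0, 1], "x": [0.0, 1.0]})
        responses = pd.DataFrame(
            {"subject_id": [0, 1], "returned": [0, 0], "y": [np.nan, np.nan]}
        )
        with pytest.raises(NoRespondersError):
            fit_em_nonignorable(frame, responses, "y", ["x"])


class TestSummarizeMechanisms:
    @pytest.mark.parametrize(
        "key, variance, rng",
        [
            (("men", "self_combat", "overall"), 0.0144, 22.5),
            (("men", "self_msa", "overall"), 0.0136, 20.4),
            (("men", "self_combat", "incentive=usd20"), 0.0117, 19.8),
            (("men", "self_msa", "incentive=usd40"), 0.0066, 14.2),
        ],
    )
    def test_published_rows_reproduce(self, key, variance, rng):
        """Printed triplets give back the printed variance (proportion
        scale) and range (percentage points)."""
        res = summarize_mechanisms(*MECHANISM_TRIPLETS[key])
        assert round(res["variance_across"], 4) == variance
        assert round(res["range_across"], 1) == rng

    @pytest.mark.parametrize(
        "key, rng",
        [
            (("women", "self_combat", "overall"), 8.6),
            (("women", "self_msa", "overall"), 1.2),
        ],
    )
    def test_published_ranges_reproduce(self, key, rng):
        res = summarize_mechanisms(*MECHANISM_TRIPLETS[key])
        assert round(res["range_across"], 1) == rng

    @given(x=st.floats(0, 100, allow_nan=False))
    def test_identical_estimates_give_zero_spread(self, x):
        res = summarize_mechanisms(x, x, x)
        assert res["variance_across"] == 0.0
        assert res["range_across"] == 0.0

    @given(
        a=st.floats(0, 100, allow_nan=False),
        b=st.floats(0, 100, allow_nan=False),
        c=st.floats(0, 100, allow_nan=False),
    )
    def test_nonnegativity_and_zero_iff_equal(self, a, b, c):
        res = summarize_mechanisms(a, b, c)
        assert res["variance_across"] >= 0.0
        assert res["range_across"] >= 0.0
        if res["variance_across"] == 0.0:
            assert a == b == c

    def test_triplet_dataclass_consistency(self):
        t = MechanismTriplet.from_estimates(89.3, 85.3, 66.8)
        assert t.variance_across == pytest.approx(0.0144, abs=5e-5)
        assert t.range_across == pytest.approx(22.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            summarize_mechanisms(-1.0, 50.0, 50.0)
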
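"""Beta distributional regression: likelihood, coding, fitting, contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.special import expit, logit

from ambycolor import design
from ambycolor.darkness import (
    beta_loglik,
    fit_darkness,
    nudge_boundary,
    predict_darkness,
    relative_effect,
)
from ambycolor.designmat import DARKNESS_TERMS, build_design_matrix
from conftest import constant_darkness_fit

COLS = [
    "intercept", "time[1h]", "time[4h]", "time[12h]",
    "mother[barbouri]", "father[barbouri]", "mother:father",
]


class TestBetaLoglik:
    def test_uniform_density_is_zero(self):
        assert beta_loglik(0.5, 0.5, 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_beta22_hand_value(self):
        # mu=0.5, phi=4 is Beta(2,2): density 6 y (1-y) = 1.125 at y=0.25
        assert beta_loglik(0.25, 0.5, 4.0) == pytest.approx(
            np.log(1.125), abs=1e-12
        )

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            mu, phi = rng.uniform(0.2, 0.8), rng.uniform(1.5, 40)
            val, _ = integrate.quad(
                lambda y: np.exp(beta_loglik(y, mu, phi)), 0, 1,
                limit=200,
            )
            assert val == pytest.approx(1.0, abs=1e-8)

    def test_boundary_rejected(self):
        for y in (0.0, 1.0):
            with pytest.raises(ValueError):
                beta_loglik(y, 0.5, 2.0)

    def test_boundary_nudge(self):
        y = nudge_boundary(np.array([0.0, 1.0, 0.5]), n_pixels=105000)
        assert 0 < y[0] < y[2] < y[1] < 1
        assert y[2] == pytest.approx(0.5, abs=1e-5)


class TestDesignMatrix:
    def test_reference_cell_all_zero(self, full_design):
        X, cols, _, _ = build_design_matrix(full_design, DARKNESS_TERMS)
        assert cols == COLS
        ref = (
            (full_design.mother == "texanum")
            & (full_design.father == "texanum")
            & (full_design.exposure_h == 0)
        ).to_numpy()
        assert (X[ref, 1:] == 0).all()
        assert (X[:, 0] == 1).all()

    def test_barbouri_cross_at_4h(self, full_design):
        X, cols, _, _ = build_design_matrix(full_design, DARKNESS_TERMS)
        row = (
            (full_design.mother == "barbouri")
            & (full_design.father == "barbouri")
            & (full_design.exposure_h == 4)
        ).to_numpy()
        expect = {c: 0.0 for c in cols}
        expect.update(
            intercept=1, **{"time[4h]": 1, "mother[barbouri]": 1,
                            "father[barbouri]": 1, "mother:father": 1}
        )
        np.testing.assert_array_equal(
            X[row][0], [expect[c] for c in cols]
        )

    def test_full_design_shape(self, full_design):
        X, _, clutch_idx, clutch_ids = build_design_matrix(full_design)
        assert X.shape == (288, 7)
        assert len(clutch_ids) == 12
        assert clutch_idx.max() == 11


class TestFitDarkness:
    def test_smoke_fit_structure_and_moment_recovery(
        self, small_obs, tiny_sampler
    ):
        fit = fit_darkness(small_obs, sampler=tiny_sampler)
        assert fit.pointwise_loglik.shape[1] == len(small_obs)
        assert np.isfinite(fit.pointwise_loglik).all()
        assert set(fit.draws) == {
            "beta_mu", "gamma_phi", "tau_mu", "tau_phi", "u_mu", "u_phi"
        }
        assert {"rhat", "ess_bulk", "ess_tail"} <= set(
            fit.diagnostics.columns
        )
        # posterior grand mean should sit near the sample mean
        cells = small_obs[["mother", "father", "exposure_h"]].drop_duplicates()
        pred = predict_darkness(fit, cells)
        merged = small_obs.merge(pred, on=["mother", "father", "exposure_h"])
        corr = np.corrcoef(
            merged.groupby(["mother", "father", "exposure_h"])["darkness"]
            .mean(),
            merged.groupby(["mother", "father", "exposure_h"])["mean"]
            .mean(),
        )[0, 1]
        assert corr > 0.7

    def test_intercept_only_matches_moment_estimate(self, tiny_sampler):
        # iid Beta data, intercept-only predictors: posterior mean of mu
        # within 3 posterior SDs of the analytic moment estimate
        rng = np.random.default_rng(3)
        d = design.generate_design(1, 24, [0])
        y = rng.beta(0.45 * 30, 0.55 * 30, size=len(d))
        obs = d.assign(darkness=y)
        fit = fit_darkness(obs, sampler=tiny_sampler, terms=())
        mu_draws = expit(fit.flat("beta_mu")[:, 0])
        assert abs(mu_draws.mean() - y.mean()) < 3 * mu_draws.std()

    def test_empty_and_boundary_rejected(self, small_obs):
        with pytest.raises(ValueError):
            fit_darkness(small_obs.iloc[:0])
        bad = small_obs.copy()
        bad.loc[bad.index[0], "darkness"] = 1.0
        with pytest.raises(ValueError):
            fit_darkness(bad)


class TestPredictionAlgebra:
    def test_zero_coefficients_predict_half(self):
        fit = constant_darkness_fit(COLS, np.zeros(7), np.zeros(7))
        cells = pd.DataFrame(
            [{"mother": "texanum", "father": "texanum", "exposure_h": 0}]
        )
        pred = predict_darkness(fit, cells)
        assert pred.loc[0, "mean"] == pytest.approx(0.5)
        assert pred.loc[0, "hdci_low"] == pred.loc[0, "hdci_high"] == 0.5

    def test_monotone_time_coefficients_give_monotone_means(self):
        beta = np.array([-0.5, 0.2, 0.5, 0.9, 0, 0, 0])
        fit = constant_darkness_fit(COLS, beta, np.zeros(7))
        cells = pd.DataFrame(
            [
                {"mother": "texanum", "father": "texanum", "exposure_h": h}
                for h in (0, 1, 4, 12)
            ]
        )
        means = predict_darkness(fit, cells)["mean"].to_numpy()
        assert (np.diff(means) > 0).all()
        np.testing.assert_allclose(
            means, expit([-0.5, -0.3, 0.0, 0.4]), atol=1e-12
        )

    def test_prediction_keeps_fit_time_coding_for_single_level_cells(self):
        # predicting only 4-h cells must still apply the 4-h time effect
        # (the reference level is the fit's, not the prediction table's)
        beta = np.array([0.0, 0.0, 1.2, 0.0, 0, 0, 0])
        fit = constant_darkness_fit(COLS, beta, np.zeros(7))
        cells = pd.DataFrame(
            [{"mother": "texanum", "father": "texanum", "exposure_h": 4}]
        )
        pred = predict_darkness(fit, cells)
        assert pred.loc[0, "mean"] == pytest.approx(expit(1.2), abs=1e-12)

    def test_relative_effect_identity_and_forced_ratio(self):
        fit = constant_darkness_fit(COLS, np.zeros(7), np.zeros(7))
        cell = {"mother": "texanum", "father": "texanum", "exposure_h": 0}
        eff = relative_effect(fit, cell, cell)
        assert eff["mean"] == pytest.approx(0.0, abs=1e-12)

        # engineer mu_a = 1.365 * mu_b via the mother coefficient
        mu_b = 0.3
        beta = np.zeros(7)
        beta[0] = logit(mu_b)
        beta[4] = logit(1.365 * mu_b) - logit(mu_b)
        fit = constant_darkness_fit(COLS, beta, np.zeros(7))
        eff = relative_effect(
            fit,
            {"mother": "barbouri", "father": "texanum", "exposure_h": 0},
            {"mother": "texanum", "father": "texanum", "exposure_h": 0},
        )
        assert eff["mean"] == pytest.approx(36.5, abs=1e-9)
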
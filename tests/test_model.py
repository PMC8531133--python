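"""Design construction, the beta-regression posterior, posterior prediction,
and the two-group Cohen's d model."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import betapsup as bp
from betapsup.model import (
    BetaRegressionPriors,
    PosteriorDraws,
    _beta_mixed_logp_and_grad,
)

from conftest import FAST_MCMC, fit_quietly


class TestBuildDesign:
    def test_exp1_spans_24_distinct_cells(self, exp1_ratings):
        prep = bp.prepare_ratings(exp1_ratings)
        design = bp.build_design(prep, "exp1")
        assert len(design.cells) == 2 * 2 * 6
        assert design.n_coef == 24
        rows = np.array([design.cell_row(c) for c in design.cells])
        assert len(np.unique(rows, axis=0)) == 24
        assert np.linalg.matrix_rank(rows) == 24

    def test_exp2to5_cells_plus_slope(self, null_config):
        prep = bp.prepare_ratings(bp.simulate_ratings(null_config.with_(n_per_group=5)))
        design = bp.build_design(prep, "exp2to5")
        assert len(design.cells) == 12
        assert design.n_coef == 13
        assert "fear_z" in design.coef_names
        # the fear_z column enters the cell row scaled by the requested value
        r0 = design.cell_row(design.cells[0], fear_z=0.0)
        r1 = design.cell_row(design.cells[0], fear_z=2.0)
        j = design.coef_names.index("fear_z")
        assert r1[j] == 2.0 and r0[j] == 0.0

    def test_reference_levels(self, null_config):
        prep = bp.prepare_ratings(bp.simulate_ratings(null_config.with_(n_per_group=5)))
        design = bp.build_design(prep, "exp2to5")
        assert design.group_levels[0] == "A"
        assert design.event_types[design.event_levels[0]] == "objective"

    def test_missing_rating_type_level_rejected(self, exp1_ratings):
        beliefs_only = exp1_ratings[exp1_ratings.rating_type == "belief"]
        with pytest.raises(ValueError, match="bet"):
            bp.build_design(bp.prepare_ratings(beliefs_only), "exp1")

    def test_missing_fear_z_rejected(self, null_config):
        df = bp.simulate_ratings(null_config.with_(n_per_group=4)).drop(columns="fear_z")
        with pytest.raises(ValueError, match="fear_z"):
            bp.build_design(df, "exp2to5")

    def test_unknown_cell_rejected(self, null_fit):
        with pytest.raises(KeyError):
            null_fit.design.cell_row(("A", "not_an_event"))


class TestLogPosterior:
    def test_gradient_matches_finite_differences(self, null_config):
        prep = bp.prepare_ratings(bp.simulate_ratings(null_config.with_(n_per_group=6)))
        design = bp.build_design(prep, "exp2to5")
        f = _beta_mixed_logp_and_grad(
            design.X, design.y, design.participant_idx,
            design.n_participants, BetaRegressionPriors(),
        )
        rng = np.random.default_rng(0)
        dim = design.n_coef + design.n_participants + 2
        x = rng.normal(0, 0.3, dim)
        _, g = f(x)
        h = 1e-6
        for i in rng.choice(dim, 15, replace=False):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            num = (f(xp)[0] - f(xm)[0]) / (2 * h)
            assert g[i] == pytest.approx(num, rel=1e-4, abs=1e-5)


def _manual_draws(design, coef, phi, sd, n_draws=50):
    """PosteriorDraws with constant parameters, for analytic checks."""
    nd = n_draws
    return PosteriorDraws(
        design=design,
        coef_draws=np.tile(coef, (nd, 1)),
        sd_participant_draws=np.full(nd, sd),
        phi_draws=np.full(nd, phi),
        participant_intercept_draws=np.zeros((nd, design.n_participants)),
        diagnostics=pd.DataFrame(),
        n_chains=1,
        converged=True,
        n_divergent=0,
        seed=0,
    )


class TestPosteriorPredict:
    def test_support_and_determinism(self, null_fit):
        cell = null_fit.design.cells[0]
        a = bp.posterior_predict(null_fit, cell, n_new=50, seed=7)
        b = bp.posterior_predict(null_fit, cell, n_new=50, seed=7)
        assert np.all((a > 0) & (a < 1))
        assert np.array_equal(a, b)

    def test_concentrates_at_cell_mean_in_low_noise_limit(self, null_fit):
        # sd_participant = 0 and phi enormous: predictive spread vanishes and
        # predictions sit at inverse-logit of the linear predictor
        design = null_fit.design
        coef = np.zeros(design.n_coef)
        coef[0] = 0.8
        draws = _manual_draws(design, coef, phi=1e7, sd=0.0)
        pred = bp.posterior_predict(draws, design.cells[0], n_new=200, seed=1)
        assert np.allclose(pred, expit(0.8), atol=5e-3)
        assert pred.std() < 1e-3

    def test_moment_identity_mu_and_phi(self, null_fit):
        # with fixed parameters, E[y] = mu and Var[y] = mu(1-mu)/(phi+1)
        design = null_fit.design
        coef = np.zeros(design.n_coef)
        coef[0] = -0.4
        phi = 7.0
        mu = expit(-0.4)
        draws = _manual_draws(design, coef, phi=phi, sd=0.0, n_draws=200)
        pred = bp.posterior_predict(draws, design.cells[0], n_new=500, seed=3)
        true_var = mu * (1 - mu) / (phi + 1)
        assert pred.mean() == pytest.approx(mu, abs=4 * np.sqrt(true_var / pred.size))
        assert pred.var() == pytest.approx(true_var, rel=0.05)


class TestFitBetaMixed:
    def test_rejects_unsquished_data(self, null_config):
        df = bp.simulate_ratings(null_config.with_(n_per_group=4))
        design = bp.build_design(df.assign(rating_squished=df.rating_raw / 100), "exp2to5")
        design.y = np.clip(design.y, 0.0, 1.0)
        design.y[0] = 0.0
        with pytest.raises(ValueError, match="squish"):
            bp.fit_beta_mixed(design)

    def test_recovers_known_group_effect(self, effect_fit, effect_config):
        # generating logit-scale group effect on objective events is -0.8
        draws = effect_fit.coef("group[B]")
        assert np.median(draws) == pytest.approx(-0.8, abs=0.15)
        lo, hi = bp.hdi(draws)
        assert lo < -0.8 < hi

    def test_null_coefficients_cover_zero(self, null_fit):
        design = null_fit.design
        names = [n for n in design.coef_names if n.startswith("group")]
        covered = 0
        for n in names:
            lo, hi = bp.hdi(null_fit.coef(n))
            covered += lo <= 0 <= hi
        assert covered >= len(names) - 1  # allow one 5% miss among 6

    def test_posterior_contracts_with_n(self, null_config):
        sds = []
        for n in (25, 100):
            cfg = null_config.with_(n_per_group=n, seed=500 + n)
            design = bp.build_design(bp.prepare_ratings(bp.simulate_ratings(cfg)), "exp2to5")
            fit = fit_quietly(design, mcmc=FAST_MCMC, seed=n)
            sds.append(fit.coef("group[B]").std())
        assert sds[1] < sds[0]

    def test_full_fidelity_fit_meets_reporting_contract(self, null_config):
        # defaults (4 chains) must reach Rhat <= 1.01 and bulk ESS >= 4000 on
        # every reported parameter, the criterion used for all reported fits
        cfg = null_config.with_(n_per_group=25, seed=77)
        design = bp.build_design(bp.prepare_ratings(bp.simulate_ratings(cfg)), "exp2to5")
        fit = bp.fit_beta_mixed(design, seed=9)
        assert fit.converged
        assert fit.diagnostics["rhat"].max() <= 1.01
        assert fit.diagnostics["ess_bulk"].min() >= 4000
        assert fit.n_divergent == 0

    def test_save_load_round_trip(self, null_fit, tmp_path):
        null_fit.save(tmp_path / "post")
        back = PosteriorDraws.load(tmp_path / "post")
        assert np.allclose(back.coef_draws, null_fit.coef_draws)
        assert np.allclose(back.phi_draws, null_fit.phi_draws)
        assert back.design.coef_names == null_fit.design.coef_names
        assert back.design.cells == null_fit.design.cells


class TestCohensD:
    def test_identical_groups_centered_at_zero(self):
        rng = np.random.default_rng(3)
        x = rng.normal(10, 2, 80)
        post = bp.fit_cohens_d(x, x.copy(), seed=1)
        assert abs(post.median) < 0.05
        assert post.hdi_low < 0 < post.hdi_high

    def test_matches_printed_snake_comparison(self):
        # moment-exact groups (n=30, 6.40, 2.88) vs (n=25, 7.16, 2.88);
        # classical pooled d = -0.264, reported Bayesian value -0.26
        a, b = bp.simulate_questionnaire_scores(
            30, 25, 6.40, 2.88, 7.16, 2.88, exact_moments=True, seed=2
        )
        post = bp.fit_cohens_d(a, b, seed=3)
        assert post.median == pytest.approx(-0.264, abs=0.05)

    def test_large_n_limit_is_classical_pooled_d(self):
        a, b = bp.simulate_questionnaire_scores(
            4000, 4000, 0.3, 1.0, 0.0, 1.2, exact_moments=True, seed=4
        )
        sp = np.sqrt((3999 * 1.0**2 + 3999 * 1.2**2) / 7998)
        post = bp.fit_cohens_d(a, b, seed=5)
        assert post.median == pytest.approx(0.3 / sp, abs=0.02)

    def test_sign_convention_first_minus_second(self):
        a, b = bp.simulate_questionnaire_scores(
            50, 50, 1.0, 1.0, 0.0, 1.0, exact_moments=True, seed=6
        )
        assert bp.fit_cohens_d(a, b, seed=7).median > 0
        assert bp.fit_cohens_d(b, a, seed=7).median < 0

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            bp.fit_cohens_d([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            bp.fit_cohens_d([1.0, 1.0], [2.0, 2.0])
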
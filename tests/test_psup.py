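"""Probability-of-superiority estimators, BCa bootstrap, HDI, and the
posterior-predictive PSup machinery."""

import itertools
import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import betapsup as bp
from betapsup.psup import PSupPosterior, bca_adjusted_level


def psup_bruteforce(x, y):
    """Independent oracle: explicit enumeration of all pairs."""
    wins = ties = 0
    for xi, yi in itertools.product(x, y):
        wins += xi > yi
        ties += xi == yi
    return (wins + 0.5 * ties) / (len(x) * len(y))


class TestEmpiricalPSup:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [1, 2, 3], 0.5),
            ([2, 4], [1, 3], 0.75),
            ([1, 2], [2, 3], 0.125),
        ],
    )
    def test_enumerated_examples(self, x, y, expected):
        assert bp.psup_empirical(x, y) == pytest.approx(expected)

    @given(
        x=st.lists(st.integers(0, 8), min_size=1, max_size=15),
        y=st.lists(st.integers(0, 8), min_size=1, max_size=15),
    )
    @settings(deadline=None, max_examples=80)
    def test_matches_bruteforce_and_complement(self, x, y):
        p = bp.psup_empirical(x, y)
        assert p == pytest.approx(psup_bruteforce(x, y), abs=1e-12)
        assert p + bp.psup_empirical(y, x) == pytest.approx(1.0, abs=1e-12)

    @given(
        x=st.lists(st.integers(1, 60), min_size=2, max_size=12),
        y=st.lists(st.integers(1, 60), min_size=2, max_size=12),
    )
    @settings(deadline=None, max_examples=50)
    def test_invariant_under_monotone_transform(self, x, y):
        # strictly increasing maps that are exact on small integers
        p = bp.psup_empirical(x, y)
        xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
        assert bp.psup_empirical(xa**3, ya**3) == pytest.approx(p, abs=1e-12)
        assert bp.psup_empirical(-1 / xa, -1 / ya) == pytest.approx(p, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bp.psup_empirical([], [1])


class TestPairedPSup:
    def test_examples(self):
        assert bp.psup_paired([1, 2, 3], [1, 2, 3]) == 0.5
        assert bp.psup_paired([3, 5, 2], [1, 4, 2]) == pytest.approx(2.5 / 3)
        assert bp.psup_paired([4, 5], [1, 2]) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="align"):
            bp.psup_paired([1, 2], [1, 2, 3])


class TestBetaClosedForm:
    def test_symmetry_and_analytic_value(self):
        assert bp.psup_beta_closed(0.3, 5, 0.3, 5) == pytest.approx(0.5, abs=1e-8)
        # X ~ Beta(2,1), Y ~ Beta(1,1): P(X > Y) = int x * 2x dx = 2/3
        assert bp.psup_beta_closed(2 / 3, 3, 0.5, 2) == pytest.approx(2 / 3, abs=1e-8)

    def test_complement_under_swap(self):
        p = bp.psup_beta_closed(0.7, 4, 0.4, 9)
        assert p + bp.psup_beta_closed(0.4, 9, 0.7, 4) == pytest.approx(1.0, abs=1e-7)

    def test_monotone_in_mu1(self):
        grid = [bp.psup_beta_closed(m, 6, 0.5, 6) for m in np.linspace(0.2, 0.8, 7)]
        assert np.all(np.diff(grid) > 0)

    def test_matches_simulation(self):
        rng = np.random.default_rng(8)
        mu1, phi1, mu2, phi2 = 0.62, 5.0, 0.45, 12.0
        x = rng.beta(mu1 * phi1, (1 - mu1) * phi1, 40_000)
        y = rng.beta(mu2 * phi2, (1 - mu2) * phi2, 40_000)
        p_mc = bp.psup_empirical(x, y)
        p_cf = bp.psup_beta_closed(mu1, phi1, mu2, phi2)
        se = np.sqrt(p_cf * (1 - p_cf) * (1 / 40_000 + 1 / 40_000))
        assert p_mc == pytest.approx(p_cf, abs=3 * se)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            bp.psup_beta_closed(0.0, 5, 0.5, 5)
        with pytest.raises(ValueError):
            bp.psup_beta_closed(0.5, -1, 0.5, 5)


class TestBcaBootstrap:
    def test_reduces_to_percentile_when_unbiased_symmetric(self):
        # z0 = 0 and acceleration = 0 leave the quantile levels untouched
        assert bca_adjusted_level(0.0, 0.0, 0.025) == pytest.approx(0.025)
        assert bca_adjusted_level(0.0, 0.0, 0.975) == pytest.approx(0.975)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        ci1 = bp.bootstrap_ci_bca(x, y, n_boot=500, seed=5)
        ci2 = bp.bootstrap_ci_bca(x, y, n_boot=500, seed=5)
        assert ci1 == ci2

    def test_degenerate_falls_back_to_percentile(self, caplog):
        with caplog.at_level(logging.WARNING, logger="betapsup.psup"):
            lo, hi = bp.bootstrap_ci_bca(np.ones(8), np.zeros(8), n_boot=200, seed=1)
        assert lo == hi == 1.0
        assert any("degenerate" in r.message for r in caplog.records)

    def test_null_coverage(self):
        # both samples from the same distribution: the interval should contain
        # PSup = 0.5 in about 95% of replications of the whole procedure
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            x, y = rng.normal(size=30), rng.normal(size=30)
            lo, hi = bp.bootstrap_ci_bca(
                x, y, n_boot=200, seed=int(rng.integers(2**31))
            )
            hits += lo <= 0.5 <= hi
        # 99% binomial band around 0.95 for 200 replications
        assert 0.89 <= hits / n_rep <= 0.995


class TestHdi:
    def test_constant_samples(self):
        assert bp.hdi([3.0, 3.0, 3.0]) == (3.0, 3.0)

    def test_normal_quantiles(self):
        z = np.random.default_rng(1).normal(size=100_000)
        lo, hi = bp.hdi(z)
        assert lo == pytest.approx(-1.96, abs=0.03)
        assert hi == pytest.approx(1.96, abs=0.03)

    @given(st.lists(st.floats(-50, 50), min_size=5, max_size=200))
    @settings(deadline=None, max_examples=60)
    def test_never_wider_than_equal_tailed(self, xs):
        # the HDI is the minimum-width window over all windows holding
        # ceil(level * n) sorted samples; the centered window is one of them
        x = np.sort(np.asarray(xs))
        lo, hi = bp.hdi(x)
        n = x.size
        k = int(np.ceil(0.95 * n))
        start = (n - k) // 2
        assert (hi - lo) <= (x[start + k - 1] - x[start]) + 1e-9

    def test_skewed_distribution_shifts_toward_mode(self):
        x = np.random.default_rng(2).exponential(size=50_000)
        lo, hi = bp.hdi(x)
        assert lo < 0.01  # HDI starts at the mode side
        assert hi < np.quantile(x, 0.975)

    def test_validation(self):
        with pytest.raises(ValueError):
            bp.hdi([1.0])


class TestPropExceeding:
    def test_examples(self):
        assert bp.prop_exceeding([0.6, 0.7, 0.9]) == 100.0
        assert bp.prop_exceeding([0.4, 0.6, 0.7, 0.8]) == 75.0
        assert bp.prop_exceeding(np.linspace(0, 1, 100_001)) == pytest.approx(50.0, abs=0.1)


class TestPosteriorPSup:
    def test_null_fit_centered_near_half(self, null_fit):
        # one realized null dataset: the event-averaged PSup should sit near
        # 0.5 (replicate-level calibration is checked separately)
        design = null_fit.design
        all_ps = [
            bp.psup_posterior(null_fit, ("A", ev), ("B", ev), n_pred=400, seed=i)
            for i, ev in enumerate(design.event_levels)
        ]
        avg = np.mean([p.draws for p in all_ps], axis=0)
        assert 0.35 < np.median(avg) < 0.65
        lo, hi = bp.hdi(avg)
        assert (hi - lo) < 0.4  # informative, not vacuous

    def test_matches_closed_form_oracle(self, effect_fit, effect_config):
        # sd_participant = 0 in the generator, so the generating PSup is the
        # closed-form beta-vs-beta value at the generating parameters
        from scipy.special import expit

        ev = "obj1"
        cfg = effect_config
        mu_a = expit(cfg.beta_intercept + cfg.event_effects[ev])
        mu_b = expit(cfg.beta_intercept + cfg.event_effects[ev] + cfg.group_effects[ev])
        truth = bp.psup_beta_closed(mu_a, cfg.phi, mu_b, cfg.phi)
        ps = bp.psup_posterior(effect_fit, ("A", ev), ("B", ev), n_pred=1000, seed=2)
        assert ps.median == pytest.approx(truth, abs=0.03)

    def test_reporting_triple_and_determinism(self, null_fit):
        ev = null_fit.design.event_levels[0]
        a = bp.psup_posterior(null_fit, ("A", ev), ("B", ev), n_pred=100, seed=9)
        b = bp.psup_posterior(null_fit, ("A", ev), ("B", ev), n_pred=100, seed=9)
        assert np.array_equal(a.draws, b.draws)
        for field in ("median", "hdi_low", "hdi_high", "prop_gt_half"):
            assert getattr(a, field) == getattr(b, field)
        assert 0 <= a.prop_gt_half <= 100
        assert a.hdi_low <= a.median <= a.hdi_high
        assert a.warnings  # fewer than 1000 posterior draws is flagged

    def test_paired_variant_couples_intercepts(self, null_fit):
        design = null_fit.design
        e1, e2 = design.event_levels[:2]
        ps = bp.psup_posterior(null_fit, ("A", e1), ("A", e2), paired=True,
                               n_pred=300, seed=3)
        assert np.all((ps.draws >= 0) & (ps.draws <= 1))


class TestPSupContrast:
    @staticmethod
    def _mock(draws):
        return PSupPosterior.from_draws(np.asarray(draws, dtype=float))

    def test_self_contrast_is_exactly_zero(self):
        a = self._mock(np.random.default_rng(0).uniform(0.4, 0.9, 500))
        c = bp.psup_contrast([a], [a])
        assert np.all(c.draws == 0.0)

    def test_arithmetic_identity(self):
        rng = np.random.default_rng(1)
        groups_a = [self._mock(rng.uniform(0, 1, 200)) for _ in range(3)]
        groups_b = [self._mock(rng.uniform(0, 1, 200)) for _ in range(3)]
        c = bp.psup_contrast(groups_a, groups_b)
        expected = np.mean([p.draws for p in groups_a], axis=0) - np.mean(
            [p.draws for p in groups_b], axis=0
        )
        assert np.allclose(c.draws, expected)

    def test_misaligned_draws_rejected(self):
        a = self._mock(np.zeros(100))
        b = self._mock(np.zeros(101))
        with pytest.raises(ValueError, match="misaligned"):
            bp.psup_contrast([a], [b])

    def test_known_sign_recovered(self, effect_fit):
        # objective events carry the group effect; subjective events do not
        design = effect_fit.design
        obj, subj = [], []
        for ev in design.event_levels:
            ps = bp.psup_posterior(effect_fit, ("A", ev), ("B", ev), n_pred=400,
                                   seed=hash(ev) % 2**31)
            (obj if design.event_types[ev] == "objective" else subj).append(ps)
        c = bp.psup_contrast(obj, subj)
        assert c.median > 0
        assert c.prop_gt_zero >= 95.0
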
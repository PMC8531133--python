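"""Shared fixtures: small synthetic experiments and scaled-down model fits.

Fits are session-scoped (each costs seconds) and use reduced sampler settings;
the full-fidelity reporting contract has its own dedicated test.
"""

import warnings

import pytest

import betapsup as bp

# scaled-down sampler settings for fits inside tests
FAST_MCMC = bp.MCMCSettings(chains=2, draws=300, tune=300)


def fit_quietly(design, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", bp.NotConvergedWarning)
        return bp.fit_beta_mixed(design, **kwargs)


@pytest.fixture(scope="session")
def null_config():
    """All generating effects zero: groups statistically identical."""
    zero = {e.event_id: 0.0 for e in bp.DEFAULT_EVENTS}
    return bp.SimConfig(
        n_per_group=30,
        event_effects=dict(zero),
        group_effects=dict(zero),
        fear_slope=0.0,
        phi=6.0,
        sd_participant=0.5,
        seed=101,
    )


@pytest.fixture(scope="session")
def effect_config():
    """Known group effect (-0.8 logit) on objective events only, no random
    intercepts, so closed-form beta PSup is the exact generating value."""
    eff = {
        e.event_id: (-0.8 if e.event_type == "objective" else 0.0)
        for e in bp.DEFAULT_EVENTS
    }
    return bp.SimConfig(
        n_per_group=100,
        group_effects=eff,
        sd_participant=0.0,
        fear_slope=0.0,
        phi=8.0,
        seed=202,
    )


@pytest.fixture(scope="session")
def null_fit(null_config):
    prep = bp.prepare_ratings(bp.simulate_ratings(null_config))
    design = bp.build_design(prep, "exp2to5")
    return fit_quietly(design, mcmc=FAST_MCMC, seed=303)


@pytest.fixture(scope="session")
def effect_fit(effect_config):
    prep = bp.prepare_ratings(bp.simulate_ratings(effect_config))
    design = bp.build_design(prep, "exp2to5")
    return fit_quietly(design, mcmc=bp.MCMCSettings(chains=2, draws=400, tune=300), seed=404)


@pytest.fixture()
def exp1_ratings():
    """Two-rating-type (belief/bet) table for the full-factorial design."""
    cfg = bp.SimConfig(
        n_per_group=12,
        rating_type_effects={e.event_id: -0.4 for e in bp.DEFAULT_EVENTS},
        seed=55,
    )
    return bp.simulate_ratings(cfg)
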
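import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import arealrisk as ar
from arealrisk.synthetic_data import EffectShape, simulate_study

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# MCMC lengths used throughout the test suite: 2 chains x 3,000 sweeps
# (1,000 burn-in, thin 2) — enough for the small lattices fitted here.
FAST_MCMC = dict(n_iter=3000, burn_in=1000, thin=2)

SUICIDE_BETAS = {"deprivation": 0.157, "fragmentation": 0.134, "rurality": 0.041}


def mcmc(seed: int, **kw) -> ar.McmcSettings:
    return ar.McmcSettings(seed=seed, **{**FAST_MCMC, **kw})


def linear_effects(betas=None) -> dict[str, EffectShape]:
    betas = SUICIDE_BETAS if betas is None else betas
    return {k: EffectShape("linear", beta=v) for k, v in betas.items()}


def self_harm_effects() -> dict[str, EffectShape]:
    """Self-harm truth: strong linear deprivation effect, weak linear
    fragmentation effect, inverted-U rurality (suburban excess)."""
    return {
        "deprivation": EffectShape("linear", beta=0.347),
        "fragmentation": EffectShape("linear", beta=0.078),
        "rurality": EffectShape("inverted_u", mode=-0.14, curvature=0.054),
    }


@pytest.fixture(scope="session")
def small_study():
    """20x20 suicide-like study with linear effects and spatial clustering."""
    lattice = ar.make_grid_lattice(20, 20)
    study = simulate_study(lattice, seed=7, effects=linear_effects(), spatial_sd=0.3)
    return study


@pytest.fixture(scope="session")
def null_study_2000():
    """40x50 study with no covariate effects and no random effects."""
    lattice = ar.make_grid_lattice(40, 50)
    return simulate_study(lattice, seed=11, spatial_sd=0.0)


@pytest.fixture(scope="session")
def covariates():
    return ("deprivation", "fragmentation", "rurality")
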
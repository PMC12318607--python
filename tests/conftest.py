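import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ambycolor import design, synthetic
from ambycolor.sampler import FitResult, SamplerConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def full_design():
    return design.generate_design()


@pytest.fixture(scope="session")
def small_design():
    """2 clutches/pairing x 2 larvae x {0,4} h: 32 rows, 8 clutches."""
    return design.generate_design(2, 2, (0, 4))


@pytest.fixture(scope="session")
def small_obs(small_design):
    return synthetic.simulate_dataset(small_design, seed=42)


@pytest.fixture
def tiny_sampler():
    return SamplerConfig(warmup=400, steps=160, thin=4, seed=0)


def constant_darkness_fit(colnames, beta, gamma, n_draws=50):
    """A degenerate darkness FitResult with every draw equal: lets the
    deterministic prediction/contrast algebra be tested exactly."""
    p = len(colnames)
    shape = (1, n_draws)
    draws = {
        "beta_mu": np.tile(np.asarray(beta, float), (*shape, 1)),
        "gamma_phi": np.tile(np.asarray(gamma, float), (*shape, 1)),
        "tau_mu": np.zeros(shape),
        "tau_phi": np.zeros(shape),
        "u_mu": np.zeros((*shape, 1)),
        "u_phi": np.zeros((*shape, 1)),
    }
    return FitResult(
        model="darkness[const]",
        draws=draws,
        pointwise_loglik=np.zeros((n_draws, 1)),
        diagnostics=pd.DataFrame(),
        converged=True,
        meta={
            "terms": ("time", "mother", "father", "mother:father"),
            "colnames": list(colnames),
            "clutch_ids": ["c1"],
            "acceptance": 1.0,
            "n_obs": 1,
        },
    )


def constant_composition_fit(colnames, B, n_draws=50):
    p = len(colnames)
    shape = (1, n_draws)
    draws = {
        "B": np.tile(np.asarray(B, float), (*shape, 1, 1)),
        "sigma_scales": np.full((*shape, 2), 1e-9),
        "sigma_corr": np.zeros(shape),
        "tau_scales": np.zeros((*shape, 2)),
        "tau_corr": np.zeros(shape),
        "U": np.zeros((*shape, 1, 2)),
    }
    return FitResult(
        model="composition[const]",
        draws=draws,
        pointwise_loglik=np.zeros((n_draws, 1)),
        diagnostics=pd.DataFrame(),
        converged=True,
        meta={
            "terms": (
                "time", "mother", "father", "mother:father",
                "mother:time", "father:time",
            ),
            "colnames": list(colnames),
            "clutch_ids": ["c1"],
            "acceptance": 1.0,
            "n_obs": 1,
        },
    )
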
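"""Shared fixtures: small simulated datasets and a fitted mixture model.

Expensive fixtures are session-scoped so the full suite performs each
simulation/fit only once.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mixdoc as mx

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def mix_params() -> mx.DoCParams:
    """Well-separated 4-class generating parameters (the comparison scenario)."""
    return mx.make_params(mean_diff_x=1.0, mean_diff_y=1.0, b_xy=0.5, b_yx=0.5)


@pytest.fixture(scope="session")
def mix_scenario(mix_params) -> mx.ScenarioConfig:
    return mx.ScenarioConfig(
        n_mz=300, n_dz=300, params=mix_params, weights=mx.MixtureWeights.equal(),
        family="mix4", seed=7, fixed_quota=True,
    )


@pytest.fixture(scope="session")
def mix_data(mix_scenario) -> mx.TwinDataset:
    return mx.simulate_dataset(mix_scenario)


@pytest.fixture(scope="session")
def mix4_fit(mix_data) -> mx.FitResult:
    return mx.fit(mix_data, "mix4", n_starts=2, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
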
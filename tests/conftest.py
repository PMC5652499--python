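import numpy as np
import pytest

from nibench import (
    BenchmarkSpec,
    DEFAULT_FAILURE_PARAMS,
    DEFAULT_MORTALITY_PARAMS,
    Dgp,
    ScenarioConfig,
)


@pytest.fixture
def spec() -> BenchmarkSpec:
    return BenchmarkSpec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def scenario(n: int, dgp: Dgp, reps: int, seed: int) -> ScenarioConfig:
    return ScenarioConfig(
        n=n,
        dgp=dgp,
        failure_params=DEFAULT_FAILURE_PARAMS,
        mortality_params=DEFAULT_MORTALITY_PARAMS if dgp is Dgp.CR else None,
        reps=reps,
        seed=seed,
    )
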
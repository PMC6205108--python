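import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ppknn_mpc import FieldConfig, MPCEngine, share_bitwise

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def field5() -> FieldConfig:
    return FieldConfig.for_parties(5)


@pytest.fixture
def engine() -> MPCEngine:
    """Canonical 5-server engine with threshold t=2."""
    return MPCEngine(n_parties=5, threshold=2, seed=1234)


@pytest.fixture
def engine_factory():
    def make(seed: int = 0, n_parties: int = 5, threshold: int = 2,
             field: FieldConfig | None = None) -> MPCEngine:
        return MPCEngine(n_parties=n_parties, threshold=threshold,
                         field=field, seed=seed)
    return make


@pytest.fixture
def share_values():
    """Bitwise-share a list of plaintext integers with the engine's dealer."""
    def do(engine: MPCEngine, values, width: int):
        return [
            share_bitwise(int(v), width, engine.t, engine.field,
                          engine._dealer_rng)
            for v in values
        ]
    return do


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
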
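import numpy as np
import pytest

from hydrovigor import (
    HydrotimeParams,
    default_lot_params,
    simulate_time_course,
)

PSI_LEVELS = (0.0, -0.2, -0.4, -0.6, -0.8)


@pytest.fixture(scope="session")
def lot_params() -> dict[str, HydrotimeParams]:
    """Per-lot hydrotime truths from the packaged parameter fixture."""
    return default_lot_params()


@pytest.fixture(scope="session")
def noiseless_panel_factory():
    """Build a replicate-pooled noiseless (fractional) panel for one truth."""

    def make(params: HydrotimeParams, n_seeds: int = 90, fractional: bool = True):
        return [
            simulate_time_course(
                params,
                psi,
                n_seeds,
                noise_mode="noiseless",
                fractional=fractional,
                replicate="pooled",
            )
            for psi in PSI_LEVELS
        ]

    return make


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230504)
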
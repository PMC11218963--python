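import numpy as np
import pytest

from compulsim import ScenarioParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def default_params():
    """A benign scenario: reliable washing, informative checking."""
    return ScenarioParams(
        p_soiling=0.3,
        p_success=0.9,
        p_detect_dirty=0.85,
        p_detect_clean=0.85,
        cost_sickness=-0.6,
        cost_wash=-0.25,
        cost_check=-0.15,
        gamma=0.9,
    )


def random_params(rng: np.random.Generator) -> ScenarioParams:
    """Uniform draw over the full parameter supports (test helper)."""
    z = rng.dirichlet((1.0, 1.0, 1.0))
    return ScenarioParams(
        p_soiling=rng.uniform(0, 1),
        p_success=rng.uniform(0, 1),
        p_detect_dirty=rng.uniform(0.5, 1),
        p_detect_clean=rng.uniform(0.5, 1),
        cost_sickness=-float(z[0]),
        cost_wash=-float(z[1]),
        cost_check=-float(z[2]),
        gamma=rng.uniform(0, 0.999),
    )
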
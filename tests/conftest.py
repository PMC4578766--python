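import logging

import numpy as np
import pytest

from bayesgrowth.likelihood import GrowthCurve
from bayesgrowth.nested_sampler import NSConfig
from bayesgrowth.synthetic_experiments import SimSpec, generate_curve, single_curve_evidence

logging.getLogger("bayesgrowth").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def clean_curve() -> GrowthCurve:
    """Noise-free 32-point curve from the default truth."""
    return generate_curve(SimSpec(sigma=0.0, seed=0))


@pytest.fixture(scope="session")
def noisy_curve() -> GrowthCurve:
    """32-point curve with 0.1 log10 units of noise."""
    return generate_curve(SimSpec(sigma=0.1, seed=7))


@pytest.fixture(scope="session")
def ns_result(noisy_curve):
    """One full single-curve nested-sampling run, shared across tests."""
    return single_curve_evidence(noisy_curve, config=NSConfig(seed=5))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_valid_params(rng: np.random.Generator, scale_range=6.0):
    """Random parameter draws satisfying the model invariants."""
    from bayesgrowth.growth_model import GrowthParams

    y0 = rng.uniform(-2, 8)
    return GrowthParams(
        y0=y0,
        mu_max=rng.uniform(0.01, 2.0),
        h0=rng.uniform(0.0, 10.0),
        ymax=y0 + rng.uniform(0.5, scale_range),
    )
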
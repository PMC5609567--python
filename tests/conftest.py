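import numpy as np
import pytest

from rampkit.toy_bundle import BundleSpec, apply_activation_pivot, build_bundle


@pytest.fixture(scope="session")
def activation_spec():
    """Default toy activation: 25° TM5/TM6 pivot about TM3 + 43° TM6 kink."""
    return BundleSpec(pivot_angle=25.0, kink_angle=43.0)


@pytest.fixture(scope="session")
def inactive_bundle(activation_spec):
    return build_bundle(activation_spec)


@pytest.fixture(scope="session")
def pivot_result(inactive_bundle, activation_spec):
    return apply_activation_pivot(inactive_bundle, activation_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
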
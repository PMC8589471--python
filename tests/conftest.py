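import numpy as np
import pytest

from interprox.features import measure_all
from interprox.synthetic import REFERENCE_SPEC, generate_tooth_pair


@pytest.fixture(scope="session")
def reference_pair():
    """Zero-noise reference molar pair with its analytic ground truth."""
    return generate_tooth_pair(REFERENCE_SPEC)


@pytest.fixture(scope="session")
def reference_record(reference_pair):
    """The reference pair re-measured by the features pipeline."""
    cloud, _ = reference_pair
    return measure_all(cloud)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
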
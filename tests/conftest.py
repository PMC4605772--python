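import numpy as np
import pytest

from klinfo.evolution import decode_genotype


@pytest.fixture(scope="session")
def rand_params():
    """A random (not behaviorally competent) circuit for dynamics tests."""
    rng = np.random.default_rng(42)
    return decode_genotype(rng.uniform(-1.0, 1.0, 23))


@pytest.fixture(scope="session")
def best_params():
    from klinfo.evolution import load_fixture

    return load_fixture("best")
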
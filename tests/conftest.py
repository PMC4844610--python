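import numpy as np
import pytest

from hypofeed.network import ParameterVector, canonical_network
from hypofeed.experiments import load_truth_table


@pytest.fixture(scope="session")
def spec():
    return canonical_network()


@pytest.fixture(scope="session")
def table():
    return load_truth_table()


@pytest.fixture(scope="session")
def archive(spec):
    """Zero-error parameterizations shipped with the package."""
    from hypofeed.optimize import load_solutions

    return load_solutions(spec)


@pytest.fixture(scope="session")
def zero_error_params(archive):
    """One reference zero-error parameterization."""
    return archive.solutions[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(20160427)


@pytest.fixture()
def random_params(spec, rng):
    n_str = len(spec.receptors)
    vals = np.concatenate([
        rng.uniform(0.0, 2.0, n_str),
        rng.uniform(-2.0, 2.0, spec.n_params - n_str),
    ])
    return ParameterVector(spec, vals)
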
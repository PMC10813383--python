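import numpy as np
import pytest
from hypothesis import settings

from glycoda import GeneratorConfig, generate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-subject default-parameter synthetic cohort, seed 11."""
    return generate_cohort(GeneratorConfig(n_subjects=400, seed=11))


@pytest.fixture(scope="session")
def default_cohort():
    """The full-size default cohort (n=1516, seed 1)."""
    return generate_cohort(GeneratorConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_compositions(rng, n, d=46, total=100.0):
    """Strictly positive random closed compositions."""
    x = rng.dirichlet(np.full(d, 2.0), size=n) * total
    return np.clip(x, 1e-8, None)
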
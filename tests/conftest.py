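import numpy as np
import pytest

from collatscore.cohort import (
    GeneratorConfig,
    apply_exclusions,
    generate_admissions,
    generate_vasculature,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def admissions(default_config):
    """One default admission cohort, shared across tests (read-only)."""
    return generate_admissions(default_config, seed=11)


@pytest.fixture(scope="session")
def analysis_cohort(admissions):
    return apply_exclusions(admissions)


@pytest.fixture
def random_sheet(rng):
    """Factory for random but valid complete grading sheets."""

    def make(burden=None):
        b = float(rng.uniform()) if burden is None else burden
        return generate_vasculature(b, rng)

    return make
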
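import numpy as np
import pytest

from methylzyg import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort under the generator's default study conditions."""
    return simulate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    """A fast cohort for IO/plumbing tests."""
    return simulate_cohort(
        CohortConfig(n_tumours=40, n_normals=12, probes_per_gene=5, seed=5)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
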
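import numpy as np
import pytest

from eqtlrx import synthdata as sd


@pytest.fixture(scope="session")
def small_spec() -> sd.CohortSpec:
    return sd.CohortSpec(
        n_families=40, family_size_range=(2, 6), n_probes=40, n_true_eqtl=10, seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return sd.generate_cohort(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
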
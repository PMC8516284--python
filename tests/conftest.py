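import warnings

import pytest

from vitdfree.binding import BindingScheme
from vitdfree.cohort import default_params, simulate_cohort
from vitdfree.config import BindingConfig
from vitdfree.indices import derive_table
from vitdfree.reference import ReferenceTable


@pytest.fixture(scope="session")
def constant_scheme() -> BindingScheme:
    return BindingConfig().constant_scheme()


@pytest.fixture(scope="session")
def allele_table() -> dict:
    return BindingConfig().allele_k_dbp


@pytest.fixture(scope="session")
def reference() -> ReferenceTable:
    return ReferenceTable.load()


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(default_params(n=146), seed=11)


@pytest.fixture(scope="session")
def small_derived(small_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return derive_table(small_cohort)


@pytest.fixture(scope="session")
def large_derived():
    """One shared n=5000 cohort with derived panel (recovery checks)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return derive_table(simulate_cohort(default_params(n=5000), seed=7))
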
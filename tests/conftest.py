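import pytest

import rxddi as rx


@pytest.fixture(scope="session")
def catalog():
    """The miniature interaction catalogue shipped with the package."""
    return rx.load_packaged_catalog()


@pytest.fixture(scope="session")
def small_cohort():
    """One small synthetic cohort shared by read-only tests."""
    return rx.generate_cohort(rx.GeneratorConfig(n_participants=800, seed=11))


@pytest.fixture(scope="session")
def small_build(small_cohort, catalog):
    return rx.build_cohort(small_cohort.events, small_cohort.covariates, catalog)
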
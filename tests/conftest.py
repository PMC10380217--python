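import pytest

from lvr.simulate import default_config, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared across the suite."""
    return simulate_cohort(default_config(seed=11))


@pytest.fixture(scope="session")
def cohort_paths(cohort, tmp_path_factory):
    """The same cohort written to disk (alignment, annotation, truth files)."""
    out = tmp_path_factory.mktemp("cohort")
    return cohort.write(out)
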
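import pytest

from prscore import (
    annotate_collection,
    default_cohort,
    load_reference_matrix,
    stratum_matrices,
)


@pytest.fixture(scope="session")
def reference_matrix():
    """The packaged 10-disease shared-gene reference as a presence matrix."""
    return load_reference_matrix()


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort (10 traits, 3 clusters, nested strata)."""
    return default_cohort(seed=7)


@pytest.fixture(scope="session")
def cohort_matrices(cohort):
    """Per-stratum presence matrices for the session cohort."""
    genemaps = annotate_collection(cohort.scores, rsid_table=cohort.universe.rsid_table)
    return stratum_matrices(cohort.scores, genemaps)


def run_cohort_pipeline(seed, **kwargs):
    """Generate a cohort and push it through annotation + matrix building."""
    c = default_cohort(seed=seed, **kwargs)
    genemaps = annotate_collection(c.scores, rsid_table=c.universe.rsid_table)
    return c, stratum_matrices(c.scores, genemaps)
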
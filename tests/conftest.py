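import pytest
from hypothesis import HealthCheck, settings

import scoliovar as sv
from scoliovar import worked_example as we

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def we_cohort() -> sv.CohortTable:
    """The 18-variant, 11-patient worked-example cohort."""
    return we.cohort()


@pytest.fixture(scope="session")
def we_rare(we_cohort) -> sv.CohortTable:
    return sv.filter_rare(sv.filter_consequence(we_cohort))


@pytest.fixture(scope="session")
def we_calls(we_rare):
    return sv.classify_cohort(we_rare)


@pytest.fixture(scope="session")
def ais_list() -> sv.GeneList:
    return sv.load_ais_gene_list()


@pytest.fixture(scope="session")
def sim_default():
    """Default synthetic cohort, fixed seed, with its truth."""
    return sv.generate_cohort(sv.SimConfig(seed=1234))


@pytest.fixture(scope="session")
def sim_rare(sim_default) -> sv.CohortTable:
    table, _ = sim_default
    return sv.filter_rare(sv.filter_consequence(table))


@pytest.fixture(scope="session")
def sim_calls(sim_rare):
    return sv.classify_cohort(sim_rare)


@pytest.fixture(scope="session")
def sim_candidates(sim_rare, sim_calls, ais_list) -> sv.GeneList:
    return sv.candidate_gene_set(sim_rare, sim_calls, ais_list)


@pytest.fixture(scope="session")
def sim_collection(sim_candidates) -> sv.GeneSetCollection:
    return sv.generate_collection(sim_candidates, seed=1235)
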
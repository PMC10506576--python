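import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pitchshift.listener_sim import default_config, simulate_cohort
from pitchshift.melody import build_experiment2_versions, lightly_row_passage
from pitchshift.si_analysis import score_responses
from pitchshift.stimulus import build_experiment1_pairs


@pytest.fixture(scope="session")
def pairs():
    return build_experiment1_pairs()


@pytest.fixture(scope="session")
def passage():
    return lightly_row_passage()


@pytest.fixture(scope="session")
def versions():
    return build_experiment2_versions()


@pytest.fixture(scope="session")
def cohort_responses():
    """One deterministic experiment-1 cohort at the study's size (19 + 20)."""
    return simulate_cohort(default_config(1), experiment=1, seed=1234)


@pytest.fixture(scope="session")
def cohort_scores(cohort_responses):
    return score_responses(cohort_responses)
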
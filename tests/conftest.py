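import pandas as pd
import pytest

from gutsig.cars_scoring import score_cohort
from gutsig.io_core import AbundanceTable, metadata_to_frame
from gutsig.synthetic_data import SimulationConfig, simulate_cohort_pair


@pytest.fixture(scope="session")
def default_pair():
    """Discovery + held-out test cohort at the default study conditions."""
    return simulate_cohort_pair(SimulationConfig(seed=1), n_test=50)


@pytest.fixture(scope="session")
def discovery(default_pair):
    return default_pair[0]


@pytest.fixture(scope="session")
def discovery_scores(discovery):
    return score_cohort(discovery.metadata)


@pytest.fixture(scope="session")
def discovery_behaviors(discovery, discovery_scores):
    behav = discovery_scores[
        [
            "cars_total",
            "social_impairment",
            "negative_emotionality",
            "distorted_sensory_response",
        ]
    ].copy()
    behav["ados_total"] = metadata_to_frame(discovery.metadata)["ados_total"]
    return behav


@pytest.fixture
def tiny_counts():
    return AbundanceTable(
        pd.DataFrame(
            [[2, 2, 4], [5, 0, 0], [1, 1, 2]],
            index=["s1", "s2", "s3"],
            columns=["gA", "gB", "gC"],
        ),
        mode="counts",
    )
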
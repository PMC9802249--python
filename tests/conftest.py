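import logging

import pytest

from yamori.models import DemographicModel, PopulationSpec, SplitEvent


@pytest.fixture(autouse=True)
def _quiet_expected_warnings(caplog):
    # summary-statistic warnings (zero-variance pairs in tiny simulations) are
    # expected noise in stress tests; keep them out of the report
    logging.getLogger("yamori").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def toy_three_pop() -> DemographicModel:
    """A (B (C)) divergence scenario: C splits from B 3,000 generations ago,
    B from A 9,000 generations ago; Ne 8,000 everywhere; 10 diploids each."""
    return DemographicModel(
        populations=(
            PopulationSpec("A", 8000, 10),
            PopulationSpec("B", 8000, 10),
            PopulationSpec("C", 8000, 10),
        ),
        splits=(SplitEvent(3000.0, "C", "B"), SplitEvent(9000.0, "B", "A")),
    )


@pytest.fixture(scope="session")
def single_pop() -> DemographicModel:
    return DemographicModel(
        populations=(PopulationSpec("A", 1000, 5),), splits=()
    )
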
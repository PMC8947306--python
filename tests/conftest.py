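from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from tdslink import AttributeVocabulary, TimeGrid

settings.register_profile(
    "fast",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fast")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def toy_log() -> Path:
    """Two-trial primary-sensory event log printed in the repo fixtures."""
    return DATA_DIR / "toy_events.csv"


@pytest.fixture
def toy_vocab() -> AttributeVocabulary:
    return AttributeVocabulary("primary-sensory", ("sweet", "sour"))


@pytest.fixture
def grid5() -> TimeGrid:
    return TimeGrid.uniform(5)
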
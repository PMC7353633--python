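import pandas as pd
import pytest
from hypothesis import settings

import milkscreen as ms
from milkscreen.schema import FEATURES

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pools():
    return ms.load_control_pools()


@pytest.fixture(scope="session")
def stats():
    return ms.load_control_stats()


@pytest.fixture(scope="session")
def boundary_sets():
    """(measured, variance_adjusted) published boundary sets."""
    return ms.load_control_boundaries()


@pytest.fixture(scope="session")
def survey():
    """(records, annotations) of the bundled market survey."""
    return ms.load_market_survey(with_annotations=True)


@pytest.fixture(scope="session")
def area_totals():
    return ms.load_survey_area_totals()


@pytest.fixture(scope="session")
def registry():
    return ms.load_adulterant_registry()


@pytest.fixture(scope="session")
def controls(pools, stats):
    """A seeded synthetic control table (15 samples)."""
    return ms.generate_controls(pools, stats, n=15, seed=42)


@pytest.fixture(scope="session")
def control_features(controls) -> pd.DataFrame:
    return controls.loc[:, list(FEATURES)]


@pytest.fixture(scope="session")
def adulterant_set(pools, registry) -> pd.DataFrame:
    return ms.make_adulterant_test_set(pools, registry)
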
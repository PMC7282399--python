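import numpy as np
import pytest

from internda import CohortConfig, load_item_map


@pytest.fixture(scope="session")
def item_map():
    return load_item_map()


@pytest.fixture(scope="session")
def recovery_config():
    """The stated five-site world at 500 children per site."""
    return CohortConfig(
        sites=[(s, 500) for s in ("Brazil", "India", "Italy", "Kenya", "UK")]
    )


@pytest.fixture(scope="session")
def small_config():
    """A cheap two-site cohort for plumbing tests (reduced oracle draws)."""
    return CohortConfig(sites=[("A", 60), ("B", 60)], oracle_draws=50_000)


def midpoint_response(item) -> int:
    return 3 if item.scale_points == 5 else 2


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
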
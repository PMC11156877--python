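import warnings

import pytest

from rxnenum.io_fixtures import fixture_pools
from rxnenum.reaction_registry import builtin, builtin_library

REACTION_IDS = [d.reaction_id for d in builtin_library()]


@pytest.fixture(scope="session")
def library():
    return builtin_library()


@pytest.fixture(scope="session")
def small_pools():
    """Fixture reagent pools (<= 5 per synthon) for every packaged reaction."""
    pools = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rid in REACTION_IDS:
            pools[rid] = fixture_pools(rid, n_per_class=5, seed=1)
    return pools


@pytest.fixture
def reaction():
    return builtin
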
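import numpy as np
import pytest

from bioprofile import SyntheticConfig, generate_world
from bioprofile.grouping import ClusterMap, DomainMap


@pytest.fixture(scope="session")
def small_world():
    """A modest synthetic screening world shared by read-only tests."""
    config = SyntheticConfig(n_compounds=300, n_targets=60, n_families=6,
                             seed=42)
    return generate_world(config)


@pytest.fixture(scope="session")
def small_world_maps(small_world):
    cmap = ClusterMap(dict(small_world.target_families))
    dmap = DomainMap({t: set(d) for t, d in small_world.domain_map.items()})
    return cmap, dmap


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
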
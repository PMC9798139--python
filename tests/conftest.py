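import numpy as np
import pytest

from twn_rencod import PlantedSite, SyntheticSpec, synthetic_binding_site


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def site16():
    """Default 16-residue (64-atom) synthetic binding site at the origin."""
    return synthetic_binding_site()


@pytest.fixture
def two_site_spec():
    """Two always-present planted TWNs, well separated, no background."""
    return SyntheticSpec(
        n_frames=5,
        planted_sites=[
            PlantedSite(center=(0.0, 0.0, 0.0)),
            PlantedSite(center=(14.0, 0.0, 0.0)),
        ],
        seed=7,
    )
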
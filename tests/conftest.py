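import pytest

from fragscreen.augment import AugmentationConfig
from fragscreen.synth import (SARGeneratorConfig, builtin_fragment_library,
                              generate_sar_dataset)


@pytest.fixture(scope="session")
def fragment_library():
    """Built-in reference fragment library at the default radius."""
    return builtin_fragment_library(3)


@pytest.fixture(scope="session")
def small_sar():
    """A small labeled seed set (12 active / 9 inactive)."""
    return generate_sar_dataset(
        SARGeneratorConfig(n_active=12, n_inactive=9, rng_seed=5))


@pytest.fixture()
def aug_config():
    return AugmentationConfig(k=5, rng_seed=11)
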
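import pytest

from cpxislands import (
    DetectionParams,
    background_model,
    island_model,
    plant_islands,
)


@pytest.fixture(scope="session")
def default_params():
    return DetectionParams()


@pytest.fixture(scope="session")
def planted():
    """30-kb synthetic genome with three planted CpG-island segments."""
    return plant_islands(
        30_000,
        [(5_000, 800), (12_000, 1_500), (20_000, 3_000)],
        background_model(),
        island_model(),
        rng_seed=7,
    )
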
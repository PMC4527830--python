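import numpy as np
import pytest

from silencescreen import Library, StrainSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_strain_library():
    """Equal-parameter pair used for symmetry/neutrality checks."""
    return Library(
        (StrainSpec("A", 30.0, 0.0), StrainSpec("B", 30.0, 0.0)),
        seed=0,
    )


@pytest.fixture
def contrast_library():
    """Wild-type-like vs +40% lifespan strain, dispersed lifespans."""
    return Library(
        (StrainSpec("wt", 30.0, 0.35), StrainSpec("long", 42.0, 0.35)),
        seed=0,
    )
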
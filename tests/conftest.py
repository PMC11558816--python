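import numpy as np
import pytest

from drivecross import CrossSpec, Lineage, SimParams


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def default_params():
    return SimParams(seed=11)


@pytest.fixture
def female_lineage_spec():
    return CrossSpec("SYN", Lineage.FEMALE_DRIVE_PARENT)


@pytest.fixture
def male_lineage_spec():
    return CrossSpec("SYN", Lineage.MALE_DRIVE_PARENT)
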
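import numpy as np
import pytest

from travelnet.cohort import (
    Beta,
    CenterGroup,
    CohortSpec,
    ConstantSizes,
    FixedTotalSizes,
    build_cohort,
    split_cohort,
)
from travelnet.network import ModelConfig, build_model
from travelnet.phantom import PhantomSpec, PhantomVolumes


TINY_MODEL = ModelConfig(
    n_conv_blocks=2, channels=(2, 3), grid_size=12, dropout_rate=0.2, init_seed=11
)


@pytest.fixture(scope="session")
def small_cohort():
    """3 centers x 8 participants, enough for engine-level tests."""
    spec = CohortSpec(
        center_size_profile=(CenterGroup("c", 3, ConstantSizes(8)),),
        master_seed=5,
    )
    return build_cohort(spec)


@pytest.fixture(scope="session")
def small_split(small_cohort):
    return split_cohort(small_cohort, seed=3)


@pytest.fixture(scope="session")
def small_volumes(small_cohort):
    spec = PhantomSpec(grid_size=12, class_effect_size=0.4, master_seed=5)
    return PhantomVolumes(small_cohort, spec)


@pytest.fixture()
def tiny_model():
    return build_model(TINY_MODEL)
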
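import numpy as np
import pytest

from gliomics import CohortSpec, MaskGrid, VolumeGrid, generate_cohort


def make_volume(values, spacing=(1.0, 1.0, 1.0)):
    return VolumeGrid(np.asarray(values, dtype=np.float64), spacing)


def make_mask(values, spacing=(1.0, 1.0, 1.0)):
    return MaskGrid(np.asarray(values, dtype=np.uint8), spacing)


def full_mask(shape, spacing=(1.0, 1.0, 1.0)):
    return MaskGrid(np.ones(shape, dtype=np.uint8), spacing)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale phantom cohort: 4+4 subjects on a 40-mm grid."""
    spec = CohortSpec(
        n_codel=4, n_noncodel=4, image_shape=(40, 40, 40), homogeneity_gap=1.5, seed=11
    )
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210706)
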
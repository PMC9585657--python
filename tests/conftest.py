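import warnings

import numpy as np
import pytest

import gliotex as g
from gliotex.pipeline import _iter_cohort, extract_cohort_features

#: compact phantom geometry used by the unit suite (fast, >=4 usable slices)
SMALL_SPEC = dict(
    n_patients=12,
    n_class_positive=4,
    volume_shape=(10, 32, 32),
    tumor_radius_range_mm=(3.0, 6.0),
)


@pytest.fixture(scope="session")
def small_cohort():
    return g.generate_phantom_cohort(g.PhantomSpec(seed=42, **SMALL_SPEC))


@pytest.fixture(scope="session")
def small_slice_table(small_cohort):
    """Slice-level 164-feature table of the compact cohort."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny polar slices are skipped
        return extract_cohort_features(_iter_cohort(small_cohort))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def textured_slice():
    """One coarse-textured tumor slice with its mask."""
    return g.generate_tumor_slice(g.TextureParams(4.0, 1.0, 0.5), seed=3)
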
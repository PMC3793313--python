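import numpy as np
import pytest

from pfavox import SyntheticSpec, generate_localizer_run


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_spec():
    """A compact single-category localizer spec used across tests."""
    return SyntheticSpec(
        n_voxels=40,
        grid_shape=(4, 4, 4),
        n_categories=1,
        strong_fraction=0.1,
        weak_fraction=0.1,
        redundancy_copies=1,
        seed=5,
    )


@pytest.fixture
def localizer(small_spec):
    ts, design, gt = generate_localizer_run(small_spec, small_spec.categories[0], seed=11)
    return ts, design, gt


@pytest.fixture
def default_localizer():
    spec = SyntheticSpec()
    ts, design, gt = generate_localizer_run(spec, spec.categories[0], seed=3)
    return spec, ts, design, gt
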
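import numpy as np
import pytest

from dcegrad.phantom import LesionSpec, PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """A fast desk-scale phantom: 6 acquisitions, 12 slices of 32x32."""
    return PhantomSpec(n_slices=12, slice_shape=(32, 32), chest_depth=6, seed=11)


@pytest.fixture
def lesioned_spec():
    """Default-geometry phantom with a strong washout lesion at slice 20."""
    return PhantomSpec(
        lesion=LesionSpec(center=(20, 30, 17)),
        bpe_fraction=0.3,
        seed=42,
    )


@pytest.fixture
def lesioned_series(lesioned_spec):
    return generate_phantom(lesioned_spec)
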
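import numpy as np
import pytest

from plotpheno import (
    SyntheticFieldSpec,
    build_canopy_mask,
    generate_scene,
)


@pytest.fixture(scope="session")
def small_spec():
    """Compact trial (15 plots) used by most imaging tests."""
    return SyntheticFieldSpec(seed=11, plot_rows=3, plot_cols=5)


@pytest.fixture(scope="session")
def default_spec():
    """The full default trial layout (135 plots)."""
    return SyntheticFieldSpec(seed=0)


@pytest.fixture(scope="session")
def scene(small_spec):
    """Reflectance-mode LBK scene on the compact trial."""
    return generate_scene(small_spec, "LBK", mode="reflectance")


@pytest.fixture(scope="session")
def scene_dn(small_spec):
    """Digital-number-mode LBK scene on the compact trial."""
    return generate_scene(small_spec, "LBK", mode="digital_number")


@pytest.fixture(scope="session")
def canopy_mask(scene):
    return build_canopy_mask(scene.stack)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
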
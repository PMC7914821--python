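import numpy as np
import pytest
from hypothesis import settings

from pollenfoci.synthetic import ChannelSpec, NucleusSpec, SyntheticSpec

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")

# a scaled-down grain geometry for fast unit tests (the full-size default
# geometry is exercised by the acceptance suite)
SMALL_GEOM = dict(
    shape=(10, 128, 128),
    voxel_size=(1.0, 0.28, 0.28),
    pollen_semiaxes=(3.5, 45.0, 45.0),
    vn=NucleusSpec((4.5, 52.0, 64.0), 2.5, 3000.0),
    sc=(
        NucleusSpec((5.5, 47.0, 70.0), 1.2, 4000.0),
        NucleusSpec((4.0, 45.0, 57.0), 1.2, 4000.0),
    ),
)


def small_spec(seed=0, f=0.1, rho=0.5, **overrides) -> SyntheticSpec:
    ch = ChannelSpec(clustered_fraction=f, foci_rate=30.0, focus_radius_um=0.3)
    params = dict(
        seed=seed,
        channels={"GFP": ch, "RFP": ch},
        coloc_rho=rho,
        **SMALL_GEOM,
    )
    params.update(overrides)
    return SyntheticSpec(**params)


@pytest.fixture
def small_stack():
    from pollenfoci.synthetic import generate_pollen_stack

    return generate_pollen_stack(small_spec(seed=17))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
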
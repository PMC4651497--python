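import pytest

import surequant as sq


@pytest.fixture(scope="session")
def spec32():
    """Desk-scale phantom: 32³ grid, geometry shrunk proportionally."""
    return sq.PhantomSpec(
        grid_shape=(32, 32, 32),
        tissue_geometry=sq.TissueGeometry(
            brain_radii_vox=(12.0, 13.0, 12.0),
            shell_thickness_vox=2.5,
            ventricle_radii_vox=(2.0, 4.0, 2.0),
            ventricle_offset_vox=3.0,
        ),
    )


@pytest.fixture(scope="session")
def template32(spec32):
    return sq.make_template_phantom(spec32)


@pytest.fixture(scope="session")
def cohort32(spec32):
    """Six controls and one lesion-free subject with anatomical variability."""
    return sq.make_cohort(spec32, 6, [None], seed=11)


@pytest.fixture(scope="session")
def cache32():
    return sq.FieldCache()
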
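import numpy as np
import pytest

import kpuumap as km


@pytest.fixture(scope="session")
def grid():
    return km.default_grid()


@pytest.fixture(scope="session")
def tissue(grid):
    return km.default_tissue_mask(grid)


@pytest.fixture(scope="session")
def atlas(grid):
    return km.default_atlas(grid)


@pytest.fixture(scope="session")
def profiles():
    return km.default_profiles()


@pytest.fixture(scope="session")
def risperidone(profiles):
    return profiles["risperidone"]


@pytest.fixture
def zero_noise():
    return km.NoiseModel.zero()


@pytest.fixture
def small_grid():
    return km.PixelGrid(n_rows=12, n_cols=15, raster_step=100.0)


@pytest.fixture
def small_section(small_grid):
    """Tiny hand-assembled two-channel section for unit tests."""
    rng = np.random.default_rng(7)
    tissue = np.zeros(small_grid.shape, dtype=bool)
    tissue[1:-1, 1:-1] = True
    analyte = rng.uniform(10, 100, small_grid.shape)
    is_img = np.full(small_grid.shape, 50.0)
    return km.SectionDataset(
        grid=small_grid,
        channels=[
            km.ChannelImage("drugX", "analyte", analyte, group="drugX"),
            km.ChannelImage("drugX-d4", "internal_standard", is_img,
                            group="drugX"),
        ],
        tissue_mask=tissue, condition="in_vivo", subject_id="s1")
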
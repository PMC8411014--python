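import numpy as np
import pytest

from tmeprog.stroma import RgbTile
from tmeprog.synthetic import CohortSpec, HeTileSpec, IhcCoreSpec, generate_cohort, generate_he_tile, generate_ihc_core


@pytest.fixture(scope="session")
def he_tile_056():
    """Reference H&E tile at the published stroma cutpoint scale (0.56)."""
    return generate_he_tile(
        HeTileSpec(width=512, height=512, target_stroma_fraction=0.56, seed=7)
    )


@pytest.fixture(scope="session")
def small_ihc_core():
    """50 brown + 150 blue well-separated nuclei."""
    return generate_ihc_core(IhcCoreSpec(n_positive=50, n_negative=150, seed=3))


@pytest.fixture(scope="session")
def cohort_600():
    """Simulated n=600 cohort at the default hazard pattern 1:1.75:2.86."""
    return generate_cohort(CohortSpec(n_patients=600, seed=42))


@pytest.fixture(scope="session")
def renderer_calibration():
    """Affine calibration of the stroma pipeline against the renderer."""
    from tmeprog.pipeline import estimate_renderer_calibration

    return estimate_renderer_calibration(seed=1000)


@pytest.fixture()
def grey_tile():
    """Flat mid-grey tile (already white balanced)."""
    px = np.full((64, 64, 3), 128, np.uint8)
    return RgbTile(px)
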
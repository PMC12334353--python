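import numpy as np
import pytest

from usinr import (
    InrConfig,
    LossConfig,
    ScanGeometry,
    TrainConfig,
    fit_inr,
    make_phantom,
    render_sweep,
)


@pytest.fixture(scope="session")
def two_sphere_phantom():
    """Two well-separated anechoic spheres in the standard field of view."""
    return make_phantom(seed=11, n_spheres=2, radius_range_mm=(8.0, 12.0),
                        anechoic=True)


@pytest.fixture(scope="session")
def small_geom(two_sphere_phantom):
    ph = two_sphere_phantom
    return ScanGeometry(180.0, 10.0, ph.axial_extent_mm, ph.lateral_extent_mm,
                        48, 48)


@pytest.fixture(scope="session")
def small_frames(two_sphere_phantom, small_geom):
    return render_sweep(two_sphere_phantom, small_geom, seed=5)


@pytest.fixture(scope="session")
def trained_small(small_frames, small_geom):
    """A small but genuinely trained model shared across sampling tests."""
    model, log = fit_inr(
        small_frames,
        small_geom,
        inr_cfg=InrConfig(pe_bands=8, n_layers=6, width=24),
        loss_cfg=LossConfig(),
        train_cfg=TrainConfig(epochs=120, seed=3),
    )
    return model, log
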
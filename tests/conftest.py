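import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter

from cardioulm.geometry import AcquisitionGeometry, CartesianGrid
from cardioulm.simulate import GroundTruth, VesselTree


@pytest.fixture(scope="session")
def geom():
    return AcquisitionGeometry()


@pytest.fixture(scope="session")
def shallow_geom():
    """Reduced imaging depth keeps RF traces short for beamforming tests."""
    return AcquisitionGeometry(imaging_depth_mm=60.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def textured_image():
    """Smooth random field with features on a ~16 px scale, range [0, 1]."""
    r = np.random.default_rng(0)
    img = gaussian_filter(r.standard_normal((128, 128)), 4)
    return (img - img.min()) / (img.max() - img.min())


@pytest.fixture(scope="session")
def small_cart_grid():
    return CartesianGrid(dz_um=67.8, dx_um=135.0, z_min_um=25e3, z_max_um=35e3,
                         x_min_um=-5e3, x_max_um=5e3)


def point_ground_truth(points, frame_rate_hz=305.0, intensities=None):
    """GroundTruth with one record per (frame, x_um, z_um) tuple."""
    rows = []
    for k, (f, x, z) in enumerate(points):
        inten = 1.0 if intensities is None else intensities[k]
        rows.append((f, k, x, z, 0.0, 0.0, inten))
    rec = pd.DataFrame(rows, columns=["frame", "id", "x_um", "z_um",
                                      "vx_mm_s", "vz_mm_s", "intensity"])
    n_frames = int(rec["frame"].max()) + 1 if len(rec) else 1
    return GroundTruth(records=rec, tree=VesselTree(), frame_rate_hz=frame_rate_hz,
                       n_frames=n_frames, seed=0)
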
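import numpy as np
import pytest

from stentoct import attenuation as att
from stentoct import segmentation as seg
from stentoct import synthetic as syn

# Compact phantom geometry reused across tests: same physics as the
# default with a reduced lateral field; full depth is kept so the
# record decays into noise, which the floor estimator relies on.
SMALL_DIMS = (64, 400, 200)
SMALL_PITCHES = (10.0, 3.0, 10.0)


@pytest.fixture(scope="session")
def small_phantom():
    """Default-pose phantom on a compact grid, with its ground truth."""
    return syn.make_stent_phantom(dims=SMALL_DIMS, pitches_um=SMALL_PITCHES, seed=0)


@pytest.fixture(scope="session")
def small_segmentation(small_phantom):
    """OAC + refined mask for the compact phantom."""
    volume, truth = small_phantom
    oac = att.compute_oac(volume)
    mask = seg.refine_mask(seg.binarize_in_roi(oac, truth.landmarks.roi))
    return volume, truth, oac, mask


@pytest.fixture(scope="session")
def small_bmscan():
    """Short BM-scan series (4 cardiac cycles) with full artifacts on."""
    return syn.make_bmscan_series(n_frames=1536, shape_zx=(32, 120), seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
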
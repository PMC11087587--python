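import numpy as np
import pytest

from octspeckle import BScan, ScanGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_geometry():
    """Reduced-size geometry with the native pixel pitches."""
    return ScanGeometry(n_lateral=200, n_axial=220)


def make_roi(intensity, geometry=None, **kwargs):
    """Wrap an intensity matrix as an already-extracted ROI."""
    intensity = np.asarray(intensity, dtype=float)
    if geometry is None:
        geometry = ScanGeometry(n_lateral=intensity.shape[1],
                                n_axial=intensity.shape[0])
    kwargs.setdefault("roi_extracted", True)
    return BScan(intensity=intensity, geometry=geometry, **kwargs)
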
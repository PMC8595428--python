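import numpy as np
import pytest

from hyperbold.volio import Mask3D, VolumeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_series(data, tr_s=1.5, voxel=(1.0, 1.0, 1.0), **kw) -> VolumeSeries:
    return VolumeSeries(data=np.asarray(data, dtype=float), voxel_size_mm=voxel, tr_s=tr_s, **kw)


@pytest.fixture
def small_mask():
    data = np.zeros((8, 8, 6), dtype=bool)
    data[1:7, 1:7, 1:5] = True
    return Mask3D(data=data)


@pytest.fixture
def small_roi():
    data = np.zeros((8, 8, 6), dtype=bool)
    data[3:6, 3:6, 2:4] = True
    return Mask3D(data=data)
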
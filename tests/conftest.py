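import numpy as np
import pytest

from logstage.imaging_io import RasterImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def step_image():
    """64x64 vertical step edge at column 32."""
    px = np.zeros((64, 64))
    px[:, 32:] = 1.0
    return RasterImage(px, source_id="step")


@pytest.fixture
def disk_image():
    """256x256 centered disk of radius 60."""
    yy, xx = np.mgrid[0:256, 0:256]
    r = np.hypot(yy - 127.5, xx - 127.5)
    return RasterImage((r <= 60).astype(float), source_id="disk")
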
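import numpy as np
import pytest

from tailquant.core import CalibratedImage, PixelCalibration


@pytest.fixture
def cal1() -> PixelCalibration:
    """Unit calibration: 1 μm per pixel, so pixel and physical units coincide."""
    return PixelCalibration(1.0)


@pytest.fixture
def blank_rgb(cal1) -> CalibratedImage:
    return CalibratedImage(np.zeros((50, 50, 3), dtype=np.uint8), cal1)
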
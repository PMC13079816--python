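import numpy as np
import pytest
from skimage import measure

from nbviability import DetectionConfig, ImageFrame


@pytest.fixture
def det_cfg():
    """Detector configuration matching the default synthetic geometry."""
    return DetectionConfig()


def connected_component_oracle(
    image: ImageFrame, threshold_au: float, background: float | None = None
):
    """Independent counting oracle: global threshold + connected components.

    Returns (count, centroids) where centroids are (row, col) floats of each
    above-threshold blob.  Used only to cross-check the ROI-scanning
    detector; shares no code with it.
    """
    px = image.pixels
    if background is None:
        background = float(np.median(px))
    labels = measure.label(px - background > threshold_au)
    props = measure.regionprops(labels)
    return len(props), np.array([p.centroid for p in props]).reshape(-1, 2)


@pytest.fixture
def cc_oracle():
    return connected_component_oracle
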
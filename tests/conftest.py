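import numpy as np
import pytest

from lungmorph import CalibrationSettings


@pytest.fixture(scope="session")
def calibration():
    """Unit scale with the synthetic palette threshold."""
    return CalibrationSettings(scale_um_per_px=1.0, threshold=150)


def match_to_truth(pipeline_labels: np.ndarray, label: int, truth) -> int:
    """Ground-truth label of a pipeline object, by majority pixel overlap.

    Connected-component labeling assigns ids in raster order, which need
    not match the generator's placement order, so correspondence is
    established by overlap rather than id.
    """
    ys, xs = np.nonzero(pipeline_labels == label)
    return int(np.bincount(truth.label_map[ys, xs]).argmax())
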
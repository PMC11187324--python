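import colorsys

import numpy as np
import pytest

from blscreen.qc import QCThresholds
from blscreen.synthetic import generate_tile


@pytest.fixture(scope="session")
def default_thresholds():
    return QCThresholds()


@pytest.fixture(scope="session")
def clean_pos_tile():
    return generate_tile(1, "clean", 64, 7)


@pytest.fixture(scope="session")
def clean_neg_tile():
    return generate_tile(0, "clean", 64, 7)


def hue_band_count(raster: np.ndarray, lo: float, hi: float, sat_floor: float = 0.0) -> int:
    """Independent per-pixel oracle: count pixels with hue in [lo, hi) degrees
    and saturation >= sat_floor, via colorsys one pixel at a time."""
    count = 0
    for row in raster.reshape(-1, 3):
        h, s, _v = colorsys.rgb_to_hsv(*(row / 255.0))
        if s >= sat_floor and lo <= h * 360.0 < hi:
            count += 1
    return count


def hsv_mask_count(raster: np.ndarray, hue, sat, val) -> int:
    """Independent per-pixel oracle for an HSV box mask."""
    count = 0
    for row in raster.reshape(-1, 3):
        h, s, v = colorsys.rgb_to_hsv(*(row / 255.0))
        hd = h * 360.0
        if hue[0] <= hd <= hue[1] and sat[0] <= s <= sat[1] and val[0] <= v <= val[1]:
            count += 1
    return count
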
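import math

import numpy as np
import pytest

from ichthyoflow.core import FeatureClass, LabeledRegion


def make_disc(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def make_ellipse(shape, center, semi_major, semi_minor, angle=0.0):
    """Solid ellipse mask; angle = major-axis direction in (row, col)."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    u = dr * math.sin(angle) + dc * math.cos(angle)
    v = -dr * math.cos(angle) + dc * math.sin(angle)
    return (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0


def region(mask, cls=FeatureClass.BODY, confidence=None):
    return LabeledRegion(cls, mask, confidence)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
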
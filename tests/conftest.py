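import numpy as np
import pytest

from relkin import (
    GISegmentation,
    ReleaseProfile,
    Segment,
    default_gi_segmentation,
)


@pytest.fixture
def paper_schedule():
    """The 9-point 0.5-48 h sampling schedule."""
    return np.array([0.5, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0, 24.0, 48.0])


@pytest.fixture
def gi_segmentation():
    return default_gi_segmentation()


@pytest.fixture
def single_segment():
    """A one-window segmentation spanning the whole 0-48 h experiment."""
    return GISegmentation((Segment("all", "all", 0.0, 48.0, 7.0),))


@pytest.fixture
def simple_profile(paper_schedule):
    """A smooth, monotone release profile over the full schedule."""
    release = np.array([8.0, 12.0, 18.0, 25.0, 35.0, 44.0, 55.0, 78.0, 92.0])
    return ReleaseProfile("demo", paper_schedule, release, n_replicates=3)
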
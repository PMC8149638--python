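import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from plaqueprox import PointSet, build_roi


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture
def open_roi():
    """10x10 all-true ROI."""
    return build_roi(np.ones((10, 10), bool), sample_id="open")


@pytest.fixture
def single_reference():
    return PointSet([[0, 0]], kind="reference", sample_id="open")
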
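import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from dlsflow.synthetic import (BandFractionSpec, FlowSignalSpec,
                               simulate_pulsatile_flow, simulate_speckle_trace)

BASELINE = (0.880, 0.054, 0.033, 0.020, 0.013)


@pytest.fixture(scope="session")
def baseline_trace():
    """10-s fast trace with the baseline band-fraction profile."""
    return simulate_speckle_trace(BandFractionSpec(BASELINE), duration=10.0, seed=11)


@pytest.fixture(scope="session")
def pulsatile_flow():
    """300-s default pulsatile flow segment with ground-truth beat times."""
    return simulate_pulsatile_flow(FlowSignalSpec(duration=300.0, seed=21))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
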
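import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import hievox as hv

# Tests synthesize at a reduced 25 kHz rate (trills/phees stay well below
# the 12.5 kHz Nyquist) to keep the suite fast; the package default remains
# 62.5 kHz.
TEST_RATE = 25_000


@pytest.fixture(scope="session")
def colony_features():
    """A small mixed-sex trill colony with extracted (reduced-bank) features.

    4 females + 4 males, 15 trills each, filtered to common features.
    """
    spec = hv.ColonySpec(
        n_females=4, n_males=4,
        calls_per_type={"trill": 15},
        sample_rate_hz=TEST_RATE, seed=42)
    waveforms, records = hv.generate_colony(spec)
    fm = hv.build_feature_matrix(waveforms, records, bank=hv.get_bank("reduced"))
    return hv.filter_common_features(fm)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
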
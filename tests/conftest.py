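import numpy as np
import pytest
from hypothesis import settings

from ctgfusion import ClassLabel, clean_fhr, segment_signal, simulate_record

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def synthetic_segment():
    """One valid cleaned 2400-sample segment from the default simulator."""
    rec = simulate_record(ClassLabel.SUSPICIOUS, seed=7)
    segs = segment_signal(clean_fhr(rec), rec.label, record_id=rec.record_id)
    assert len(segs) == 1
    return segs[0]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
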
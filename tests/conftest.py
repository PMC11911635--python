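import numpy as np
import pytest
from hypothesis import settings

from phenocage import HomecageSimSpec, SegmentationConfig, TrackingTrace

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")
from phenocage.geometry import phenotyper_arena


@pytest.fixture(scope="session")
def seg_cfg():
    return SegmentationConfig()


@pytest.fixture(scope="session")
def day_spec():
    """One simulated home-cage day at a reduced sample rate."""
    return HomecageSimSpec(seed=11, duration_days=1, sample_rate=5.0)


@pytest.fixture(scope="session")
def three_day_spec():
    return HomecageSimSpec(seed=23, duration_days=3, sample_rate=5.0)


def make_trace(x, y, sample_rate=5.0, arena=None, zone=None):
    x = np.asarray(x, dtype=float)
    n = len(x)
    return TrackingTrace(
        times=np.arange(n) / sample_rate,
        x=x,
        y=np.asarray(y, dtype=float),
        sample_rate=sample_rate,
        zone=zone,
        arena=arena,
    )


@pytest.fixture()
def homecage_arena():
    return phenotyper_arena()
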
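import numpy as np
import pytest

from microedtk import AcquisitionPlan, DetectorSpec


@pytest.fixture
def small_spec() -> DetectorSpec:
    """A 32x32 detector with the standard frame/reset timing."""
    return DetectorSpec(width=32, height=32)


@pytest.fixture
def short_plan() -> AcquisitionPlan:
    """A 2 s, 0.5 s/image rotation plan scaled down for fast simulation."""
    return AcquisitionPlan(
        exposure_time=2.0,
        summation_window=0.5,
        rotation_rate=0.2,
        pixel_size_mm=0.028,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
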
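import numpy as np
import pytest

from pupilload.io import PupilTrace
from pupilload.preprocess import CleanTrace, FLAG_RAW, BaselineEstimate


def make_clean_trace(d, rate_hz=60.0, t=None, pid="p00", tag="measurement"):
    """CleanTrace from a diameter list; NaN entries are missing samples."""
    d = np.asarray(d, dtype=float)
    if t is None:
        t = np.arange(d.size) * (1000.0 / rate_hz)
    flags = np.where(np.isfinite(d), FLAG_RAW, 3).astype(np.uint8)
    return CleanTrace(t, d, flags, rate_hz, pid, tag)


def make_pupil_trace(d_left, d_right=None, rate_hz=60.0, pid="p00",
                     tag="measurement"):
    d_left = np.asarray(d_left, dtype=float)
    if d_right is None:
        d_right = d_left.copy()
    t = np.arange(d_left.size) * (1000.0 / rate_hz)
    return PupilTrace(t, d_left, np.asarray(d_right, dtype=float),
                      rate_hz, pid, tag)


@pytest.fixture
def baseline30():
    return BaselineEstimate(mean_d=30.0, window=(0.0, 2000.0), n_valid=120)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
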
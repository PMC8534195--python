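import numpy as np
import pytest

from usvkit.synth import SessionDesign, synthesize_session

FS = 250_000.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_session():
    """One 2-min session (1 min baseline + 1 min post) at 20 dB SNR."""
    design = SessionDesign(baseline_minutes=1.0, post_minutes=1.0, snr_db=20.0)
    wave, records = synthesize_session(design, 5)
    return design, wave, records


@pytest.fixture(scope="session")
def short_session_contours(short_session):
    from usvkit.detect import detect_session

    design, wave, records = short_session
    return detect_session(wave, FS)
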
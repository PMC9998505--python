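import numpy as np
import pytest
from hypothesis import settings

from hdotools.detection import extract_features, train_detector
from hdotools.spectral import HDOBand
from hdotools.synth import benchmark_courses

settings.register_profile("ci", max_examples=25, derandomize=True,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def band():
    """Consensus band at the cohort-mean oscillation parameters."""
    return HDOBand(f_o=0.20, sigma=0.025)


@pytest.fixture(scope="session")
def trained_detector(band):
    """Detector trained once per session on the 226-course synthetic set."""
    courses, labels = benchmark_courses(113, 113, seed=2026)
    feats = [extract_features(tc, band) for tc in courses]
    return train_detector(feats, labels, seed=7)
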
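import numpy as np
import pytest

from obnvc.core import Channel
from obnvc.session import write_session
from obnvc.synth import SessionConfig, make_ground_truth, synthesize_session


@pytest.fixture(scope="session")
def small_session():
    """Default-noise paired BV/Ca session at reduced (32x32) image size."""
    cfg = SessionConfig(height=32, width=32, dtype="float32")
    movies, truth = synthesize_session(cfg, seed=123)
    return movies, truth


@pytest.fixture(scope="session")
def small_session_dir(small_session, tmp_path_factory):
    movies, truth = small_session
    d = tmp_path_factory.mktemp("session")
    write_session(movies, d, truth)
    return d


@pytest.fixture(scope="session")
def clean_truth():
    """Noise- and drift-free ground truth for exact round-trip checks."""
    cfg = SessionConfig(height=16, width=16, noise_sd_frac=0.0,
                        bleach_amp_frac=0.0)
    return make_ground_truth(cfg, seed=7)
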
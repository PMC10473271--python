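import numpy as np
import pytest

from arrowtime import signal_io as sio
from arrowtime import synthetic as syn


@pytest.fixture(scope="session")
def ou_family():
    """Five OU systems sharing S, K across graded asymmetry levels."""
    return syn.make_ou_family(10, [0, 0.25, 0.5, 1, 2], seed=42)


@pytest.fixture(scope="session")
def ramp_cohort():
    """Noise-free monotone cohort, z-scored: the maximally irreversible fixture."""
    cohort = [syn.make_ramp_series(10, 176, 0.0, seed=100 + i,
                                   participant_id=f"p{i:02d}")
              for i in range(20)]
    return [sio.normalize_series(s) for s in cohort]


@pytest.fixture(scope="session")
def noise_cohort():
    """Iid Gaussian cohort: forward and reversed windows exchangeable."""
    cohort = [syn.make_noise_series(10, 176, seed=200 + i,
                                    participant_id=f"p{i:02d}")
              for i in range(20)]
    return [sio.normalize_series(s) for s in cohort]


@pytest.fixture(scope="session")
def tiny_patterns():
    """Small separable pattern set for fast classifier unit tests."""
    from arrowtime import windowing as win

    cohort = [sio.normalize_series(
        syn.make_ramp_series(2, 60, 0.0, seed=300 + i,
                             participant_id=f"q{i:02d}"))
        for i in range(6)]
    ds = win.build_dataset(cohort, "global", 10, 5)
    return next(iter(ds.values()))
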
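import numpy as np
import pytest

from wristfog import (
    GeneratorConfig,
    WindowConfig,
    build_dataset,
    synthesize_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """3 subjects, 120 s sessions: enough windows for classifier tests."""
    return synthesize_cohort(GeneratorConfig(n_subjects=3, session_s=120, seed=7))


@pytest.fixture(scope="session")
def small_windows(small_cohort):
    windows, scales = build_dataset(
        small_cohort.recordings, small_cohort.tracks, WindowConfig()
    )
    return windows


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
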
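import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from suturemetrics import CohortConfig, generate_cohort, cohort_frame


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter cohort (45 trials), generated once per session."""
    cfg = CohortConfig()
    trials = generate_cohort(cfg, seed=7)
    return cfg, trials


@pytest.fixture(scope="session")
def default_cohort_frame(default_cohort):
    cfg, trials = default_cohort
    return cohort_frame(trials, cfg, measure="annotation")
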
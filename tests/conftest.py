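import numpy as np
import pytest

from cgmentropy import CohortSpec, generate_cohort, load_fixtures


@pytest.fixture(scope="session")
def fixture_tables():
    """Published per-record SampEn scores and LOO rows."""
    return load_fixtures()


@pytest.fixture(scope="session")
def fixture_scores(fixture_tables):
    """ScoreSet of the 23 six-day records (14 A1 / 9 B1)."""
    return fixture_tables.scoreset()


@pytest.fixture(scope="session")
def small_cohort():
    """One-day synthetic cohort, small enough for fast sweeps."""
    spec = CohortSpec(n_a1=6, n_b1=5, days=1, seed=11)
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
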
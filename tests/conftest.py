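import pytest

from timecellmap import LearningConfig, make_fixture_population


@pytest.fixture
def fig2_t10():
    """Five symmetric cells bracketing a 10 s criterion: peaks 4,6,8,12,14 s."""
    return make_fixture_population("fig2_T10")


@pytest.fixture
def fig2_t30():
    """Scaled-by-3 counterpart for a 30 s criterion: peaks 12,18,24,36,42 s."""
    return make_fixture_population("fig2_T30")


@pytest.fixture
def sparse_t10():
    """Sparse asymmetric coverage of a 10 s criterion: peaks 6,8,12,20,30 s."""
    return make_fixture_population("sparse_T10")


@pytest.fixture
def cfg_t10():
    """One learning trial toward T = 10 s with the default epsilon."""
    return LearningConfig(criterion=10.0, epsilon=0.5, n_trials=1)
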
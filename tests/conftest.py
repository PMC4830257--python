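import numpy as np
import pytest

from pvforensics.peeking import PeekingDesign, simulate_condition


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def _condition(delta, tau, n_keep, peeking, seed, return_all=False):
    design = PeekingDesign(delta=delta, tau=tau, seed=seed)
    return simulate_condition(design, n_keep, peeking=peeking, return_all=return_all)


@pytest.fixture(scope="session")
def cond_nopeek_null_het():
    """No peeking, d ~ Normal(0, 0.15): the heterogeneous null condition."""
    return _condition(0.0, 0.15, 200_000, peeking=False, seed=1001, return_all=True)


@pytest.fixture(scope="session")
def cond_nopeek_d05():
    """No peeking, fixed d = 0.5."""
    return _condition(0.5, 0.0, 200_000, peeking=False, seed=1002, return_all=True)


@pytest.fixture(scope="session")
def cond_peek_null():
    """Peeking, d = 0 exactly (pure optional-stopping inflation)."""
    return _condition(0.0, 0.0, 400_000, peeking=True, seed=1003)


@pytest.fixture(scope="session")
def cond_peek_d02():
    """Peeking, fixed d = 0.2."""
    return _condition(0.2, 0.0, 200_000, peeking=True, seed=1004)


@pytest.fixture(scope="session")
def cond_peek_d05_het():
    """Peeking, d ~ Normal(0.5, 0.15)."""
    return _condition(0.5, 0.15, 200_000, peeking=True, seed=1005)


def pytest_configure(config):
    from hypothesis import settings

    settings.register_profile("deterministic", derandomize=True)
    settings.load_profile("deterministic")
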
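import numpy as np
import pytest

from selbias import AllocationSequence, DesignParams, PolicySpec


@pytest.fixture
def worked_params() -> DesignParams:
    """K=3 arms, one block of length 6 — the worked-example design."""
    return DesignParams(3, 2, 1)


@pytest.fixture
def worked_seq(worked_params) -> AllocationSequence:
    """The printed 6-patient sequence (1,2,1,3,3,2)."""
    return AllocationSequence(np.array([1, 2, 1, 3, 3, 2]), worked_params)


@pytest.fixture
def policy_i() -> PolicySpec:
    return PolicySpec("I", frozenset({1}))


@pytest.fixture
def policy_ii() -> PolicySpec:
    return PolicySpec("II", frozenset({2, 3}))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260903)
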
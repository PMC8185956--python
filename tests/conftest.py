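import numpy as np
import pytest

from baycann.doe import PriorSpec
from baycann.emulator import AnnWeights, ScalingSpec
from baycann.nathist import LifeTable, NaturalHistoryParams


@pytest.fixture(scope="session")
def base_params() -> NaturalHistoryParams:
    return NaturalHistoryParams()


@pytest.fixture(scope="session")
def life_table() -> LifeTable:
    return LifeTable.default()


@pytest.fixture(scope="session")
def priors() -> PriorSpec:
    return PriorSpec.default()


@pytest.fixture(scope="session")
def tiny_network(priors):
    """A small random network with its scaling, used as a stand-in emulator.

    Random weights define a perfectly known input-output map, so posterior
    self-consistency can be checked without the cost of training.
    """
    rng = np.random.default_rng(20240917)
    I, J, K, O = 9, 16, 16, 36
    weights = AnnWeights(
        rng.normal(0.0, 0.45, (J, I)), rng.normal(0.0, 0.1, J),
        rng.normal(0.0, 0.35, (K, J)), rng.normal(0.0, 0.1, K),
        rng.normal(0.0, 0.35, (O, K)), rng.normal(0.0, 0.1, O))
    scaling = ScalingSpec(priors.lower.copy(), priors.upper.copy(),
                          np.zeros(O), np.ones(O))
    return weights, scaling
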
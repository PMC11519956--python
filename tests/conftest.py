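import numpy as np
import pytest

from ucgmem.forcefield import ForceFieldParams


@pytest.fixture(scope="session")
def ff_optimal() -> ForceFieldParams:
    """The printed optimal parameter set (epsilon = 5.788 kBT at 315 K)."""
    return ForceFieldParams.optimal()


@pytest.fixture(scope="session")
def ff_small_cutoff() -> ForceFieldParams:
    """Same energetics with a reduced cutoff, so small test boxes satisfy
    the minimum-image requirement L > 2*rc."""
    return ForceFieldParams(
        epsilon=15.159, r_min=1.095, r_shift_on=1.3, r_cut=1.6,
        k_bond=1997.0, k_angle=264.0,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
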
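import numpy as np
import pytest

from octnvep.model import TuneConfig
from octnvep.synth import SyntheticConfig, simulate_study


@pytest.fixture(scope="session")
def smoke_study():
    """Small fast synthetic study (L=60, n=40)."""
    return simulate_study(SyntheticConfig.smoke(), seed=11)


@pytest.fixture(scope="session")
def default_study():
    """Full-size synthetic study (L=557, n=150)."""
    return simulate_study(seed=1)


@pytest.fixture(scope="session")
def fast_tune():
    """Reduced inner-CV shape so tuned fits stay quick in tests."""
    return TuneConfig(grid=tuple(np.logspace(-4, 0, 15)), folds=3, repeats=1)


@pytest.fixture(scope="session")
def packaged_sequence():
    from octnvep.datasets import load_octn2_sequence

    return load_octn2_sequence()


@pytest.fixture(scope="session")
def packaged_topology():
    from octnvep.datasets import load_octn2_topology

    return load_octn2_topology()
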
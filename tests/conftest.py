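import numpy as np
import pytest

from fibrefuse.gradients import GradientScheme, generate_directions


@pytest.fixture(scope="session")
def dirs60():
    return generate_directions(60, seed=3, iters=150)


@pytest.fixture(scope="session")
def dirs250():
    return generate_directions(250, seed=6, iters=120)


@pytest.fixture(scope="session")
def scheme250(dirs250):
    """One b~0 volume plus a 250-direction b = 4 ms/um^2 shell."""
    return GradientScheme(
        np.vstack([np.zeros(3), dirs250]), np.r_[0.0, np.full(250, 4.0)]
    )


@pytest.fixture(scope="session")
def scheme60(dirs60):
    return GradientScheme(
        np.vstack([np.zeros(3), dirs60]), np.r_[0.0, np.full(60, 4.0)]
    )
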
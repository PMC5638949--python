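import numpy as np
import pytest

from srnet import Connectome, GeneratorConfig, generate_random_connectome


@pytest.fixture
def line3():
    """Three nodes in a line, both edges weight 2: strengths (2, 4, 2)."""
    w = np.array([[0, 2, 0], [2, 0, 2], [0, 2, 0]], dtype=float)
    return Connectome(w)


@pytest.fixture
def line3_heavy():
    """Three-node line with edge weights 3, used for hand-computed inputs."""
    w = np.array([[0, 3, 0], [3, 0, 3], [0, 3, 0]], dtype=float)
    return Connectome(w)


@pytest.fixture(scope="session")
def small_net():
    """A 40-node generated network, cheap enough for repeated simulation."""
    return generate_random_connectome(
        GeneratorConfig(n_nodes=40, degree_mean=8, degree_sd=2,
                        weight_mean=0.5, weight_sd=0.12, seed=11)
    )


@pytest.fixture(scope="session")
def default_net():
    """The default 114-node Gaussian random network (one fixed seed)."""
    return generate_random_connectome(GeneratorConfig(seed=1))
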
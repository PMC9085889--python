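import numpy as np
import pytest

from mcmflow.synthetic import SyntheticConfig, default_coupling


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    """Miniature study: fast to simulate, fine for mechanics checks."""
    return SyntheticConfig(
        grid_shape=(12, 12, 6),
        n_frames_bold=80,
        n_frames_pet=60,
        n_asl_pairs=6,
        n_subjects_training=3,
        n_subjects_control=3,
        seed=7,
    )


@pytest.fixture
def null_coupling():
    """Coupling map without any learning effect (static 0.5 everywhere)."""
    rho = default_coupling()
    return {k: 0.5 for k in rho}
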
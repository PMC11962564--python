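import numpy as np
import pytest

from scapreli import GeneratorConfig, generate_dataset


@pytest.fixture
def small_dataset():
    """Balanced 3 x 3 x 3 synthetic study with realistic noise."""
    cfg = GeneratorConfig(n_scapulae=3, seed=11)
    dataset, truth = generate_dataset(cfg)
    return dataset, truth, cfg


@pytest.fixture
def zero_noise_dataset():
    """Every digitization equals the posed template exactly."""
    cfg = GeneratorConfig(
        n_scapulae=2, sd_scapula=0.0, sd_observer=0.0, sd_measure=0.0,
        sd_residual=0.0, seed=5,
    )
    dataset, truth = generate_dataset(cfg)
    return dataset, truth, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random proper rotation via QR (test utility)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
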
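import numpy as np
import pytest

from dtamix.config import load_config
from dtamix.simulate import SimConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Very small model config for fast unit tests."""
    return load_config(preset="desk", l_p=24, l_d=8, c_p=8, c_d=8, c_s=8,
                       kernel_lk=(3, 5, 7), kernel_2d=3, conv_groups=2,
                       fcfp_bits=64, we_vocab_size=64, head_hidden=(16, 8))


@pytest.fixture(scope="session")
def small_sim():
    cfg = SimConfig(n_proteins=10, n_drugs=5, n_pairs=20,
                    protein_length_range=(20, 40), motif_length=6,
                    n_motif_classes=3, noise_sd=0.1, seed=7)
    return generate_dataset(cfg)


def numeric_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar f at x (oracle for autodiff)."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f(x)
        flat[i] = orig - eps
        lo = f(x)
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g
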
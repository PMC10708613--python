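import numpy as np
import pytest

from cptseg.networks import NetworkConfig, build_model
from cptseg.synthetic_data import PhantomSpec, generate_dataset


def finite_difference_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar f at x (independent oracle)."""
    g = np.zeros_like(x, dtype=float)
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


@pytest.fixture(scope="session")
def tiny_model():
    """Reduced-width C-PT network for forward/gradient tests."""
    cfg = NetworkConfig.desk_scale("cpt", depth=1)
    return build_model(cfg, seed=0)


@pytest.fixture(scope="session")
def phantom_split():
    spec = PhantomSpec(n_cases=3, slices_per_case=4, seed=7)
    return generate_dataset(spec)
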
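import numpy as np
import pytest

from hsipipe import DesignSpec, default_wavelengths, generate_experiment


@pytest.fixture(scope="session")
def design():
    return DesignSpec(seed=42)


@pytest.fixture(scope="session")
def experiment(design):
    """One seeded default experiment shared across the suite."""
    return generate_experiment(design)


@pytest.fixture(scope="session")
def wavelengths():
    return default_wavelengths()


def planted_signal(seed: int, n: int = 90, p: int = 176, noise: float = 0.1,
                   bands=(10, 50)):
    """y built from two known bands of an iid Gaussian X, plus noise."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    y = sum(X[:, b] for b in bands) + noise * rng.standard_normal(n)
    return X, y
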
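import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from qsarws.dataset import DescriptorTable
from qsarws.synthetic_data import default_mgmt_like_spec, generate

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_table(X: np.ndarray, y: np.ndarray, names=None) -> DescriptorTable:
    """Wrap plain arrays into a DescriptorTable for module-level APIs."""
    n, p = X.shape
    names = names or [f"x{j}" for j in range(p)]
    idx = pd.Index([f"C{i:03d}" for i in range(n)], name="id")
    return DescriptorTable(
        pd.DataFrame(X, index=idx, columns=names),
        pd.Series(y, index=idx),
    )


def planted_linear(rng, n=50, p=5, active=(0, 1), coefs=(2.0, -1.0), noise=0.1):
    """Random design with a known sparse linear response."""
    X = rng.normal(size=(n, p))
    y = 1.0 + X[:, list(active)] @ np.asarray(coefs) + rng.normal(0, noise, n)
    return X, y


@pytest.fixture(scope="session")
def mgmt_study():
    """One study-shaped synthetic dataset shared across read-only tests."""
    table, truth = generate(default_mgmt_like_spec(seed=42))
    return table, truth


@pytest.fixture()
def rng():
    # fresh, order-independent stream per test
    return np.random.default_rng(2026)
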
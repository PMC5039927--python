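import numpy as np
import pytest

from gptime import CellMetadata, ExpressionMatrix, Hyperparameters, simulate_dataset


@pytest.fixture
def hyper():
    return Hyperparameters(
        mu_psi=0.0, sigma_psi=0.5, mu_omega=-2.3, sigma_omega=0.5,
        length_scale=1.0, sigma_tau=0.5,
    )


@pytest.fixture
def small_dataset(hyper):
    """A small synthetic dataset (G=5, C=12, T=4) for fast contract tests."""
    return simulate_dataset(5, 12, 4, 1.0, hyper, seed=42)


@pytest.fixture
def tiny_matrix():
    rng = np.random.default_rng(0)
    values = rng.normal(size=(3, 4))
    return ExpressionMatrix(["G1", "G2", "G3"], ["C1", "C2", "C3", "C4"], values)


@pytest.fixture
def tiny_meta():
    return CellMetadata(["C1", "C2", "C3", "C4"], [1.0, 1.0, 2.0, 2.0])
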
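import numpy as np
import pytest

from scggm.model import CGGMModel, SufficientStats


def random_pd_matrix(p: int, rng: np.random.Generator, density: float = 0.5) -> np.ndarray:
    """Random symmetric positive-definite matrix via diagonal dominance."""
    A = rng.uniform(-1.0, 1.0, size=(p, p)) * (rng.random((p, p)) < density)
    A = 0.5 * (A + A.T)
    np.fill_diagonal(A, 0.0)
    d = np.abs(A).sum(axis=1) + rng.uniform(0.5, 1.5, size=p)
    A[np.diag_indices(p)] = d
    return A


def random_model(p: int, q: int, rng: np.random.Generator,
                 theta_density: float = 0.5) -> CGGMModel:
    Lam = random_pd_matrix(p, rng)
    Theta = rng.standard_normal((q, p)) * (rng.random((q, p)) < theta_density)
    return CGGMModel(Lambda=Lam, Theta=Theta)


def random_stats(p: int, q: int, n: int, rng: np.random.Generator) -> SufficientStats:
    X = rng.standard_normal((n, q))
    X = (X - X.mean(0)) / X.std(0)
    Y = rng.standard_normal((n, p))
    Y = Y - Y.mean(0)
    return SufficientStats.from_arrays(X, Y)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
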
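import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def finite_difference_jacobian(f, x0: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Dense Jacobian of a flat-vector map f: R^n -> R^n by central differences."""
    x0 = np.asarray(x0, dtype=np.float64).ravel()
    n = x0.size
    f0 = np.asarray(f(x0)).ravel()
    J = np.zeros((f0.size, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = eps
        J[:, i] = (np.asarray(f(x0 + e)).ravel() - np.asarray(f(x0 - e)).ravel()) / (2 * eps)
    return J


def fd_slogdet(f, x0: np.ndarray, eps: float = 1e-6) -> float:
    """Sign-log-determinant of the finite-difference Jacobian."""
    J = finite_difference_jacobian(f, x0, eps)
    sign, logdet = np.linalg.slogdet(J)
    assert sign != 0, "singular Jacobian"
    return float(logdet)
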
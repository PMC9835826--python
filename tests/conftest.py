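import numpy as np
import pytest

from mwhf.basis import build_basis
from mwhf.tree import Domain, project


@pytest.fixture(scope="session")
def basis5():
    return build_basis(5)


@pytest.fixture(scope="session")
def unit_domain16():
    return Domain(np.zeros(3), 16.0)


def gaussian(alpha=1.0, center=(0.0, 0.0, 0.0), amplitude=1.0):
    center = np.asarray(center, dtype=float)

    def f(pts):
        return amplitude * np.exp(-alpha * np.sum((pts - center) ** 2, axis=-1))

    return f


@pytest.fixture(scope="session")
def gauss_tree(basis5, unit_domain16):
    """Unit Gaussian projected at 1e-5 (shared; treat as read-only)."""
    return project(gaussian(), unit_domain16, 1e-5, basis5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)


def random_gaussian_mix_tree(rng, basis, domain, prec=1e-4, n_terms=3, spread=3.0):
    """A random localized test function (mixture of a few Gaussians)."""
    centers = rng.uniform(-spread, spread, size=(n_terms, 3))
    alphas = rng.uniform(0.5, 2.0, size=n_terms)
    amps = rng.uniform(-1.0, 1.0, size=n_terms)

    def f(pts):
        out = np.zeros(pts.shape[:-1])
        for c, a, w in zip(centers, alphas, amps):
            out += w * np.exp(-a * np.sum((pts - c) ** 2, axis=-1))
        return out

    return project(f, domain, prec, basis)


@pytest.fixture(scope="session")
def h_scf_state():
    """Converged hydrogen atom at the working precision (shared, read-only)."""
    from mwhf.scf import Molecule, ScfConfig, scf_solve

    mol = Molecule.from_symbols(["H"], [np.zeros(3)])
    return scf_solve(mol, ScfConfig(precision=1e-4, max_iter=25))


@pytest.fixture(scope="session")
def he_scf_state():
    """Converged helium atom at the working precision (shared, read-only)."""
    from mwhf.scf import Molecule, ScfConfig, scf_solve

    mol = Molecule.from_symbols(["He"], [np.zeros(3)])
    return scf_solve(mol, ScfConfig(precision=1e-4, max_iter=25))


@pytest.fixture(scope="session")
def he_hf_reference():
    """Independent He restricted-HF oracle: even-tempered s-Gaussian basis.

    All integrals (overlap, kinetic, nuclear attraction, two-electron)
    have closed forms for concentric s-Gaussians, so this is a few lines
    of dense linear algebra converging to the basis-set limit.
    """
    nbas, a0, ratio, Z = 28, 0.015, 2.0, 2.0
    a = a0 * ratio ** np.arange(nbas)
    p = a[:, None] + a[None, :]
    S = (np.pi / p) ** 1.5
    q = a[:, None] * a[None, :] / p
    T = 3 * q * S
    V = -Z * 2 * np.pi / p
    P = p[:, :, None, None]
    Q = p[None, None, :, :]
    ERI = 2 * np.pi**2.5 / (P * Q * np.sqrt(P + Q))
    h = T + V
    w, U = np.linalg.eigh(S)
    X = U @ np.diag(w**-0.5) @ U.T
    F, E_old = h, 0.0
    for _ in range(200):
        _, Co = np.linalg.eigh(X @ F @ X)
        c = (X @ Co)[:, 0]
        D = np.outer(c, c)
        J = np.einsum("ijkl,kl->ij", ERI, D)
        K = np.einsum("ikjl,kl->ij", ERI, D)
        F = h + 2 * J - K
        E = 2 * np.sum(D * h) + 2 * np.sum(D * J) - np.sum(D * K)
        if abs(E - E_old) < 1e-12:
            break
        E_old = E
    return float(E)
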
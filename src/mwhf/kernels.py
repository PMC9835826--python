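"""Separated (sum-of-Gaussians) representations of radial convolution kernels.

The Poisson kernel ``1/r`` and the bound-state Helmholtz kernel
``exp(-mu r) / (4 pi r)`` -- the Green's function of ``(-nabla^2/2 - eps)``
with ``mu = sqrt(-2 eps)`` -- both admit the integral representation

    exp(-mu r)/r = (2/sqrt(pi)) * int exp(-r^2 e^{2s} - mu^2 e^{-2s}/4 + s) ds

over the real line.  Discretizing with the trapezoid rule on a
sufficiently wide ``s`` window produces a sum of Gaussians
``sum_t w_t exp(-beta_t r^2)`` whose relative error is uniform over a
finite range ``[r_min, r_max]``; the step is refined until a requested
tolerance is certified on a dense logarithmic grid.  Each Gaussian term
factorizes over Cartesian directions, which is what makes separable
multiwavelet convolution possible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SeparatedKernel", "fit_kernel", "helmholtz_mu"]

MAX_TERMS = 400
DEFAULT_EPSILON_FLOOR = 0.05


@dataclass
class SeparatedKernel:
    """Sum-of-Gaussians kernel ``K(r) ~ sum_t w_t exp(-beta_t r^2)``."""

    weights: np.ndarray
    exponents: np.ndarray
    valid_range: tuple
    rel_error: float  # certified on valid_range
    mu: float = 0.0  # decay parameter; 0 selects the Poisson kernel 1/r

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.exponents = np.asarray(self.exponents, dtype=float)
        if np.any(self.weights <= 0) or np.any(self.exponents <= 0):
            raise ValueError("kernel weights and exponents must be positive")
        if not (np.all(np.isfinite(self.weights)) and np.all(np.isfinite(self.exponents))):
            raise ValueError("kernel weights and exponents must be finite")

    @property
    def n_terms(self) -> int:
        return len(self.weights)

    def evaluate(self, r) -> np.ndarray:
        """Evaluate the Gaussian expansion at radii ``r``."""
        r = np.asarray(r, dtype=float)
        return np.exp(
            -self.exponents[None, ...] * r[..., None] ** 2
        ) @ self.weights

    def reference(self, r) -> np.ndarray:
        """The exact kernel: ``1/r`` for mu = 0, else ``exp(-mu r)/(4 pi r)``."""
        r = np.asarray(r, dtype=float)
        if self.mu == 0.0:
            return 1.0 / r
        return np.exp(-self.mu * r) / (4.0 * np.pi * r)

    def max_rel_error(self, n_grid: int = 400) -> float:
        """Maximum relative error on a dense log grid over the valid range."""
        r = np.geomspace(self.valid_range[0], self.valid_range[1], n_grid)
        return float(np.max(np.abs(self.evaluate(r) - self.reference(r)) / self.reference(r)))

    def export_text(self, path: str):
        """Two-column text dump (weight, exponent) for inspection."""
        with open(path, "w") as fh:
            fh.write(f"# separated kernel mu={self.mu} range={self.valid_range} "
                     f"rel_error={self.rel_error:.3e}\n")
            fh.write("# weight\texponent\n")
            for w, b in zip(self.weights, self.exponents):
                fh.write(f"{w:.16e}\t{b:.16e}\n")


def _trapezoid_terms(mu: float, r_min: float, r_max: float, tol: float, h: float):
    delta = tol / 10.0
    s_hi = 0.5 * np.log((np.log(1.0 / delta) + 5.0) / r_min**2)
    s_lo = np.log(delta / (2.0 * r_max))
    if mu > 0.0:
        # the exp(-mu^2 e^{-2s}/4) factor kills the integrand at small s
        s_lo = max(s_lo, -0.5 * np.log(4.0 * (np.log(1.0 / delta) + 5.0) / mu**2) - 1.5)
    s = np.arange(s_lo, s_hi + h, h)
    beta = np.exp(2.0 * s)
    logw = s - 0.25 * mu**2 * np.exp(-2.0 * s)
    w = (2.0 / np.sqrt(np.pi)) * h * np.exp(logw)
    if mu > 0.0:
        w = w / (4.0 * np.pi)
    keep = w > 0.0
    return w[keep], beta[keep]


def fit_kernel(
    mu: float, r_min: float, r_max: float, rel_error: float, max_terms: int = MAX_TERMS
) -> SeparatedKernel:
    """Fit a sum-of-Gaussians expansion of ``1/r`` (mu = 0) or ``e^{-mu r}/(4 pi r)``.

    The trapezoid step of the integral representation is halved until the
    expansion meets ``rel_error`` on a dense log grid over
    ``[r_min, r_max]``; terms with negligible contribution on the range
    are trimmed afterwards.

    Raises
    ------
    RuntimeError
        If the tolerance cannot be met within ``max_terms`` terms; the
        message reports the error actually achieved.
    """
    if not (0.0 < r_min < r_max):
        raise ValueError("need 0 < r_min < r_max")
    if rel_error <= 0:
        raise ValueError("rel_error must be positive")
    if mu < 0:
        raise ValueError("mu must be non-negative")

    r_grid = np.geomspace(r_min, r_max, 400)
    ref = (
        1.0 / r_grid if mu == 0.0 else np.exp(-mu * r_grid) / (4.0 * np.pi * r_grid)
    )

    h = 0.7
    best_err = np.inf
    while True:
        w, beta = _trapezoid_terms(mu, r_min, r_max, rel_error, h)
        approx = np.exp(-np.outer(r_grid**2, beta)) @ w
        err = float(np.max(np.abs(approx - ref) / ref))
        if err <= rel_error:
            break
        best_err = min(best_err, err)
        h *= 0.65
        if len(w) * 2 > max_terms:
            raise RuntimeError(
                f"kernel fit needs more than {max_terms} terms; "
                f"achieved relative error {best_err:.3e} (requested {rel_error:.3e})"
            )

    # trim terms that contribute nothing anywhere on the range
    contrib = w[None, :] * np.exp(-np.outer(r_grid**2, beta)) / ref[:, None]
    keep = np.max(contrib, axis=0) > rel_error / (100.0 * len(w))
    w, beta = w[keep], beta[keep]
    approx = np.exp(-np.outer(r_grid**2, beta)) @ w
    err = float(np.max(np.abs(approx - ref) / ref))
    if err > rel_error:
        raise RuntimeError(
            f"kernel fit failed after trimming: achieved {err:.3e} "
            f"(requested {rel_error:.3e})"
        )
    return SeparatedKernel(
        weights=w,
        exponents=beta,
        valid_range=(r_min, r_max),
        rel_error=err,
        mu=mu,
    )


def helmholtz_mu(
    orbital_energy: float, epsilon_floor: float = DEFAULT_EPSILON_FLOOR
) -> float:
    """Decay parameter of the bound-state Helmholtz kernel, ``mu = sqrt(-2 eps)``.

    Non-negative orbital energies (which occur in early SCF iterations
    from a poor guess) are guarded by a positive floor:
    ``eps >= -epsilon_floor`` maps to ``mu = sqrt(2 epsilon_floor)``.
    """
    eps = float(orbital_energy)
    if eps < -epsilon_floor:
        return float(np.sqrt(-2.0 * eps))
    return float(np.sqrt(2.0 * epsilon_floor))
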
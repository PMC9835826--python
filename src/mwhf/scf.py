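"""Restricted Hartree-Fock by the integral (bound-state Helmholtz) formulation.

Instead of diagonalizing a discretized Fock operator, each occupied
orbital is updated through the Green's function of the shifted kinetic
energy operator,

    phi_i  <-  -2 G_{mu_i} * ( V phi_i - sum_{j != i} F_ij phi_j ),
    G_mu(r) = exp(-mu r) / (4 pi r),   mu_i = sqrt(-2 F_ii),

which is a preconditioned fixed-point iteration converging to the SCF
solution without ever applying a Laplacian.  The kinetic matrix is
obtained gradient-free from the same identity: if ``phi~_i = -2 G * g_i``
then ``(T - eps_i) phi~_i = -g_i``, so ``<phi~_i|T|phi~_j> =
-<phi~_i|g_j> + eps_j <phi~_i|phi~_j>``; the initial iteration uses the
analytic kinetic integrals of the Gaussian guess.

The nuclear attraction uses a smoothed point-charge potential
``-Z u(r/c)/c`` whose error integrates to high order against s-type
densities; the smoothing length is tied to the requested precision.
All two-electron machinery (Coulomb, exchange with pair screening and
reference-function local thresholds) is built from tree multiplications
and separated Poisson convolutions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .algebra import (
    OrbitalSet,
    add,
    matrix_elements_blocked,
    multiply,
    rotate,
)
from .basis import MultiwaveletBasis, build_basis
from .convolution import apply as conv_apply
from .convolution import build_reference_screen
from .kernels import (
    DEFAULT_EPSILON_FLOOR,
    SeparatedKernel,
    fit_kernel,
    helmholtz_mu,
)
from .screening import ScreeningLedger, pair_count
from .tree import Domain, FunctionTree, project

# internal operations run tighter than the SCF rung so the fixed-point
# noise floor sits safely below the convergence threshold
OP_FACTOR = 0.2

__all__ = [
    "Molecule",
    "ScfConfig",
    "ScfState",
    "ScfError",
    "initial_guess",
    "nuclear_potential",
    "coulomb_potential",
    "exchange_apply",
    "fock_matrix",
    "helmholtz_update",
    "orthonormalize",
    "localize_foster_boys",
    "scf_solve",
]

ELEMENTS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18,
}


class ScfError(RuntimeError):
    pass


@dataclass
class Molecule:
    """Nuclei (restricted closed-shell; one-electron systems also allowed)."""

    atoms: list  # (symbol, Z, position[3] in bohr)
    charge: int = 0
    multiplicity: int = 1

    def __post_init__(self):
        self.atoms = [
            (sym, int(z), np.asarray(pos, dtype=float)) for sym, z, pos in self.atoms
        ]
        ne = self.n_electrons
        if ne < 1:
            raise ValueError("molecule has no electrons")
        if ne % 2 == 1 and ne != 1:
            raise ValueError(
                "restricted closed-shell treatment requires an even electron count "
                "(single-electron systems are the only exception)"
            )

    @classmethod
    def from_symbols(cls, symbols, positions, charge: int = 0) -> "Molecule":
        atoms = []
        for sym, pos in zip(symbols, positions):
            if sym not in ELEMENTS:
                raise ValueError(f"unknown element symbol {sym!r}")
            atoms.append((sym, ELEMENTS[sym], pos))
        return cls(atoms=atoms, charge=charge)

    @property
    def n_electrons(self) -> int:
        return sum(z for _, z, _ in self.atoms) - self.charge

    @property
    def n_occupied(self) -> int:
        return max(1, self.n_electrons // 2) if self.n_electrons > 1 else 1

    def nuclear_repulsion(self) -> float:
        e = 0.0
        for a in range(len(self.atoms)):
            for b in range(a + 1, len(self.atoms)):
                r = np.linalg.norm(self.atoms[a][2] - self.atoms[b][2])
                e += self.atoms[a][1] * self.atoms[b][1] / r
        return e

    def extent_center(self):
        pos = np.array([p for _, _, p in self.atoms])
        lo, hi = pos.min(axis=0), pos.max(axis=0)
        return float(np.max(hi - lo)), 0.5 * (lo + hi)


def default_domain(mol: Molecule, padding: float = 8.0) -> Domain:
    """Cubic box: molecular extent plus twice the padding, centered on the nuclei."""
    ext, center = mol.extent_center()
    return Domain(center, ext + 2.0 * padding)


# ----------------------------------------------------------------------
# nuclear potential
# ----------------------------------------------------------------------


def _u_smooth(r):
    """High-order smoothed 1/r profile: erf core plus Gaussian corrections."""
    r = np.asarray(r, dtype=float)
    rr = np.maximum(r, 1e-30)
    core = np.where(r < 1e-10, 2.0 / math.sqrt(math.pi), erf(rr) / rr)
    return core + (np.exp(-(r**2)) + 16.0 * np.exp(-4.0 * r**2)) / (
        3.0 * math.sqrt(math.pi)
    )


def smoothing_length(z: int, prec: float) -> float:
    """Per-atom smoothing length: energy error per atom stays below ~prec/100."""
    return min(0.1, (prec * 17.6) ** (1.0 / 4.6)) / z


def nuclear_potential(
    mol: Molecule, domain: Domain, prec: float, basis: MultiwaveletBasis
) -> FunctionTree:
    """Smoothed nuclear attraction ``sum_A -Z_A u(|r - R_A|/c_A)/c_A`` as a tree."""
    cs = [smoothing_length(z, prec) for _, z, _ in mol.atoms]

    def v(pts):
        out = np.zeros(pts.shape[:-1])
        for (sym, z, pos), c in zip(mol.atoms, cs):
            r = np.sqrt(np.sum((pts - pos) ** 2, axis=-1))
            out -= (z / c) * _u_smooth(r / c)
        return out

    # the potential is unnormalized and deep; scale the threshold to the
    # density-weighted error rather than the raw potential norm
    return project(v, domain, prec, basis, norm_hint=1.0)


# ----------------------------------------------------------------------
# Gaussian guess (s-type), with analytic one-electron integrals
# ----------------------------------------------------------------------


def _gauss_s_integrals(exponents, centers, mol: Molecule):
    """Overlap, kinetic, and point-nuclear attraction for s-Gaussians."""
    m = len(exponents)
    S = np.empty((m, m))
    T = np.empty((m, m))
    V = np.zeros((m, m))
    for a in range(m):
        for b in range(m):
            p = exponents[a] + exponents[b]
            q = exponents[a] * exponents[b] / p
            R2 = float(np.sum((centers[a] - centers[b]) ** 2))
            s = (math.pi / p) ** 1.5 * math.exp(-q * R2)
            S[a, b] = s
            T[a, b] = q * (3.0 - 2.0 * q * R2) * s
            P = (exponents[a] * centers[a] + exponents[b] * centers[b]) / p
            for _, z, C in mol.atoms:
                x = p * float(np.sum((P - C) ** 2))
                f0 = 1.0 if x < 1e-12 else 0.5 * math.sqrt(math.pi / x) * erf(
                    math.sqrt(x)
                )
                V[a, b] -= z * (2.0 * math.pi / p) * math.exp(-q * R2) * f0
    return S, T, V


def _guess_basis(mol: Molecule):
    """Atom-centered s-type Gaussians with hydrogenic exponents."""
    exps, centers = [], []
    for _, z, pos in mol.atoms:
        a1 = (8.0 / (9.0 * math.pi)) * z * z  # best single-Gaussian 1s
        shells = [a1]
        if z > 2:
            shells += [a1 / 8.0, a1 / 32.0]
        elif z > 1:
            pass
        for a in shells:
            exps.append(a)
            centers.append(np.asarray(pos, dtype=float))
    return np.array(exps), centers


def _initial_guess(mol: Molecule, prec: float, basis, domain):
    """Orthonormalized Gaussian guess orbitals plus their analytic kinetic matrix."""
    nocc = mol.n_occupied
    exps, centers = _guess_basis(mol)
    if len(exps) < nocc:
        raise ScfError(
            f"guess basis has {len(exps)} functions but {nocc} occupied orbitals "
            "are required"
        )
    S, T, V = _gauss_s_integrals(exps, centers, mol)
    evals, evecs = np.linalg.eigh(S)
    if evals.min() <= 1e-10:
        raise ScfError("guess overlap matrix is numerically singular")
    Sih = evecs @ np.diag(evals**-0.5) @ evecs.T
    h = Sih @ (T + V) @ Sih
    _, U = np.linalg.eigh(h)
    C = Sih @ U[:, :nocc]  # columns: occupied guess orbitals

    trees = []
    for i in range(nocc):
        coef = C[:, i]

        def fi(pts, coef=coef):
            out = np.zeros(pts.shape[:-1])
            for cval, a, cen in zip(coef, exps, centers):
                r2 = np.sum((pts - cen) ** 2, axis=-1)
                out += cval * np.exp(-a * r2)
            return out

        trees.append(project(fi, domain, prec, basis))
    occ = np.full(nocc, 2.0)
    if mol.n_electrons == 1:
        occ[:] = 1.0
    oset = OrbitalSet(trees, occ)
    Tmat = C.T @ T @ C
    oset = orthonormalize(oset, prec)  # projection slightly perturbs the overlap
    return oset, Tmat


def initial_guess(mol: Molecule, prec: float, order: int = 5, padding: float = 8.0):
    """Atom-centered, symmetrically orthonormalized Gaussian guess orbitals."""
    basis = build_basis(order)
    domain = default_domain(mol, padding)
    oset, _ = _initial_guess(mol, prec, basis, domain)
    return oset


# ----------------------------------------------------------------------
# kernels (cached per precision/range)
# ----------------------------------------------------------------------

_KERNEL_CACHE: dict = {}


def poisson_kernel(domain: Domain, prec: float) -> SeparatedKernel:
    r_max = math.sqrt(3.0) * domain.edge
    key = ("poisson", round(math.log10(prec), 3), round(r_max, 3))
    if key not in _KERNEL_CACHE:
        _KERNEL_CACHE[key] = fit_kernel(0.0, 1e-4, r_max, prec)
    return _KERNEL_CACHE[key]


def bsh_kernel(mu: float, domain: Domain, prec: float) -> SeparatedKernel:
    mu = max(round(mu, 6), 1e-3)
    r_max = min(math.sqrt(3.0) * domain.edge, (math.log(1.0 / prec) + 12.0) / mu)
    key = ("bsh", mu, round(math.log10(prec), 3), round(r_max, 3))
    if key not in _KERNEL_CACHE:
        _KERNEL_CACHE[key] = fit_kernel(mu, 1e-4, r_max, prec)
    return _KERNEL_CACHE[key]


# ----------------------------------------------------------------------
# Coulomb and exchange
# ----------------------------------------------------------------------


def density(oset: OrbitalSet, prec: float) -> FunctionTree:
    """Total electron density ``rho = sum_i occ_i |phi_i|^2``."""
    rho = None
    for occ, phi in zip(oset.occupations, oset.orbitals):
        sq = multiply(phi, phi, prec)
        rho = sq.scale(occ) if rho is None else add(rho, sq, 1.0, occ)
    return rho


def coulomb_potential(oset: OrbitalSet, prec: float) -> FunctionTree:
    """Hartree potential: Poisson convolution of the total density."""
    rho = density(oset, prec)
    return conv_apply(poisson_kernel(oset.domain, prec), rho, prec)


def exchange_apply(
    oset: OrbitalSet,
    target_index: int,
    prec: float,
    ledger: ScreeningLedger | None = None,
    use_screen: bool = True,
    pair_threshold: float | None = None,
    potential_cache: dict | None = None,
) -> FunctionTree:
    """Exact-exchange action ``K phi_i = sum_j phi_j P[phi_j phi_i]``.

    Screening: (a) pairs whose orbital product norm falls below the pair
    threshold (default ``prec / sqrt(n_pairs)``) are neglected outright
    and counted in the ledger; (b) each Poisson application carries a
    reference screen built from both pair partners, so the same
    potential serves ``K phi_i`` and ``K phi_j`` (pass a shared
    ``potential_cache`` to reuse it); (c) the per-term precision is
    tightened by ``1/sqrt(N_occ)`` so the summed error stays at ``prec``.
    """
    i = target_index
    n = len(oset)
    npairs = max(pair_count(n), 1)
    pthr = pair_threshold if pair_threshold is not None else prec / math.sqrt(npairs)
    term_prec = prec / math.sqrt(n)
    phi_i = oset.orbitals[i]
    out = None
    for j in range(n):
        phi_j = oset.orbitals[j]
        key = (min(i, j), max(i, j))
        cached = potential_cache.get(key) if potential_cache is not None else None
        if cached is None:
            rho_ij = multiply(phi_i, phi_j, term_prec)
            if i != j and rho_ij.norm() <= pthr:
                if ledger is not None and j > i:
                    ledger.count_pair(False)
                continue
            if ledger is not None and j > i:
                ledger.count_pair(True)
            screen = (
                build_reference_screen([phi_i, phi_j], term_prec)
                if use_screen
                else None
            )
            v_ij = conv_apply(
                poisson_kernel(oset.domain, term_prec), rho_ij, term_prec, screen
            )
            if potential_cache is not None:
                potential_cache[key] = v_ij
        else:
            v_ij = cached
        contrib = multiply(phi_j, v_ij, term_prec)
        out = contrib if out is None else add(out, contrib, 1.0, 1.0)
    if out is None:
        out = FunctionTree(oset.basis, oset.domain, prec)
    return out


# ----------------------------------------------------------------------
# Fock matrix
# ----------------------------------------------------------------------


def _kinetic_heat(oset: OrbitalSet, prec: float, t: float = 2e-3) -> np.ndarray:
    """Gradient-free kinetic matrix via the heat semigroup.

    ``<i|T|j> = lim_{t->0} (S_ij - <i| e^{t Lap} j>) / (2 t)``; a single
    Richardson step in ``t`` removes the leading error.  Diagnostic-grade
    accuracy (used when no better route is available).
    """

    def tmat(tt):
        K = SeparatedKernel(
            np.array([(4.0 * math.pi * tt) ** -1.5]),
            np.array([1.0 / (4.0 * tt)]),
            (1e-6, math.sqrt(3.0) * oset.domain.edge),
            1.0,
            0.0,
        )
        sm = [conv_apply(K, phi, prec * 0.1) for phi in oset.orbitals]
        S = matrix_elements_blocked(oset, oset)
        G = matrix_elements_blocked(oset, OrbitalSet(sm, oset.occupations.copy()))
        return (S - G) / (2.0 * tt)

    T1 = tmat(t)
    T2 = tmat(t / 2.0)
    return 2.0 * T2 - T1


def _potential_matrices(oset, vnuc, prec, ledger=None, use_screen=True,
                        potential_cache=None):
    """(V_nuc, J, K) matrices plus the per-orbital potential-applied trees."""
    n = len(oset)
    one_electron = oset.occupations.sum() <= 1.0 + 1e-12
    vn_phi = [multiply(vnuc, phi, OP_FACTOR * prec) for phi in oset.orbitals]
    Vn = matrix_elements_blocked(
        oset, OrbitalSet(vn_phi, oset.occupations.copy()), ledger
    )
    if one_electron:
        zeros = np.zeros((n, n))
        return Vn, zeros, zeros, vn_phi, None, [None] * n
    J = coulomb_potential(oset, OP_FACTOR * prec)
    j_phi = [multiply(J, phi, OP_FACTOR * prec) for phi in oset.orbitals]
    Jm = matrix_elements_blocked(
        oset, OrbitalSet(j_phi, oset.occupations.copy()), ledger
    )
    k_phi = [
        exchange_apply(
            oset, i, prec, ledger, use_screen, potential_cache=potential_cache
        )
        for i in range(n)
    ]
    Km = matrix_elements_blocked(
        oset, OrbitalSet(k_phi, oset.occupations.copy()), ledger
    )
    vtot_phi = [
        add(add(vn_phi[i], j_phi[i], 1.0, 1.0), k_phi[i], 1.0, -1.0) for i in range(n)
    ]
    return Vn, Jm, Km, vtot_phi, J, k_phi


def fock_matrix(
    oset: OrbitalSet,
    mol: Molecule,
    prec: float,
    kinetic: np.ndarray | None = None,
    ledger: ScreeningLedger | None = None,
    strict: bool = False,
) -> np.ndarray:
    """Fock matrix ``F = <i| T + V_nuc + J - K |j>``, Hermitized by averaging.

    The potential parts are assembled with node-blocked matrix elements.
    If no kinetic matrix is supplied (e.g. from the Helmholtz-update
    identity or the analytic guess), the heat-semigroup route is used.
    """
    basis, domain = oset.basis, oset.domain
    vnuc = nuclear_potential(mol, domain, prec, basis)
    Vn, Jm, Km, _, _, _ = _potential_matrices(oset, vnuc, prec, ledger)
    T = kinetic if kinetic is not None else _kinetic_heat(oset, prec)
    F = T + Vn + Jm - Km
    asym = float(np.max(np.abs(F - F.T)))
    if strict and asym > 100.0 * prec:
        raise ScfError(f"Fock matrix asymmetry {asym:.3e} exceeds 100*prec")
    return 0.5 * (F + F.T)


# ----------------------------------------------------------------------
# orthonormalization and localization
# ----------------------------------------------------------------------


def lowdin_matrix(S: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(S)
    if evals.min() <= 0.0:
        raise ScfError(
            f"overlap matrix not positive definite (smallest eigenvalue {evals.min():.3e})"
        )
    return evecs @ np.diag(evals**-0.5) @ evecs.T


def orthonormalize(oset: OrbitalSet, prec: float) -> OrbitalSet:
    """Loewdin symmetric orthonormalization ``phi <- S^{-1/2} phi`` via rotate."""
    S = matrix_elements_blocked(oset, oset)
    return rotate(oset, lowdin_matrix(S), prec)


def dipole_matrices(oset: OrbitalSet) -> list:
    """``<phi_i | r_d | phi_j>`` for d = x, y, z, exact over the union grid."""
    basis, domain = oset.basis, oset.domain
    n = basis.n
    X0 = np.einsum(
        "q,q,qp,qr->pr",
        basis.quad_w,
        basis.quad_x,
        basis.eval_scaling(basis.quad_x),
        basis.eval_scaling(basis.quad_x),
    )
    norb = len(oset)
    idxs = set()
    for t in oset.orbitals:
        idxs |= set(t.nodes)
    leaves = [i for i in idxs if all(c not in idxs for c in
              [(i[0] + 1, 2 * i[1] + bx, 2 * i[2] + by, 2 * i[3] + bz)
               for bx in (0, 1) for by in (0, 1) for bz in (0, 1)])]
    memos = [dict() for _ in range(norb)]
    out = [np.zeros((norb, norb)) for _ in range(3)]
    corner = domain.corner
    for idx in leaves:
        s_, l = idx[0], idx[1:]
        h = domain.edge / 2**s_
        S = [oset.orbitals[i].scaling_on(idx, memos[i]) for i in range(norb)]
        flat = np.stack([x.reshape(-1) for x in S])
        ov = flat @ flat.T
        for d in range(3):
            contr = [np.tensordot(X0, x, axes=(1, d)) for x in S]
            # tensordot(X0, x, (1, d)) puts the contracted axis first
            mom = np.stack(
                [np.moveaxis(c, 0, d).reshape(-1) for c in contr]
            )
            out[d] += (corner[d] + l[d] * h) * ov + h * (flat @ mom.T)
    return out


@dataclass
class LocalizationResult:
    orbitals: OrbitalSet
    unitary: np.ndarray
    converged: bool
    sweeps: int
    objective: float


def localize_foster_boys(
    oset: OrbitalSet,
    tol: float = 1e-6,
    max_sweeps: int = 50,
    prec: float | None = None,
) -> LocalizationResult:
    """Foster-Boys localization by Jacobi 2x2 sweeps.

    Maximizes ``sum_i <i|r|i>^2`` (equivalent to minimizing the summed
    second central moments for an orthonormal set); the objective is
    monotone non-decreasing by construction since each pair rotation is
    accepted only if it improves it.
    """
    norb = len(oset)
    X = dipole_matrices(oset)
    U = np.eye(norb)

    def objective():
        return sum(float(np.sum(np.diag(x) ** 2)) for x in X)

    converged = False
    sweeps = 0
    for sweep in range(max_sweeps):
        sweeps = sweep + 1
        improved = 0.0
        for i in range(norb):
            for j in range(i + 1, norb):
                A = sum(
                    x[i, j] ** 2 - 0.25 * (x[i, i] - x[j, j]) ** 2 for x in X
                )
                B = sum(x[i, j] * (x[i, i] - x[j, j]) for x in X)
                if abs(A) < 1e-300 and abs(B) < 1e-300:
                    continue
                gamma = 0.25 * math.atan2(B, -A)
                best_gain, best_gamma = 0.0, None
                f0 = objective()
                for g in (gamma, gamma + math.pi / 4.0, gamma - math.pi / 4.0):
                    c, s = math.cos(g), math.sin(g)
                    gain = _fb_gain(X, i, j, c, s) - f0
                    if gain > best_gain:
                        best_gain, best_gamma = gain, g
                if best_gamma is None or best_gain <= tol * max(abs(f0), 1.0) * 1e-6:
                    continue
                c, s = math.cos(best_gamma), math.sin(best_gamma)
                R = np.eye(norb)
                R[i, i] = R[j, j] = c
                R[i, j] = s
                R[j, i] = -s
                for d in range(3):
                    X[d] = R @ X[d] @ R.T
                U = R @ U
                improved += best_gain
        if improved <= tol * max(objective(), 1.0):
            converged = True
            break
    p = prec if prec is not None else max(oset.orbitals[0].prec, 1e-10)
    new = rotate(oset, U, p) if not np.allclose(U, np.eye(norb)) else oset.copy()
    return LocalizationResult(new, U, converged, sweeps, objective())


def _fb_gain(X, i, j, c, s):
    tot = 0.0
    for x in X:
        xii = c * c * x[i, i] + s * s * x[j, j] + 2 * c * s * x[i, j]
        xjj = s * s * x[i, i] + c * c * x[j, j] - 2 * c * s * x[i, j]
        tot += xii**2 + xjj**2
        tot += float(np.sum(np.diag(x) ** 2)) - x[i, i] ** 2 - x[j, j] ** 2
    return tot


# ----------------------------------------------------------------------
# SCF driver
# ----------------------------------------------------------------------


@dataclass
class ScfConfig:
    precision: float = 1e-4
    order: int = 5
    box_padding: float = 8.0
    ladder: list = None  # e.g. [1e-3, 1e-4]; strictly decreasing
    max_iter: int = 40
    residual_threshold: float = None  # default 10 * precision
    screening: bool = True
    localize: bool = False
    epsilon_floor: float = DEFAULT_EPSILON_FLOOR
    seed: int = 0

    def __post_init__(self):
        if self.precision <= 0:
            raise ValueError("precision must be positive")
        if self.ladder is not None:
            if list(self.ladder) != sorted(self.ladder, reverse=True) or len(
                set(self.ladder)
            ) != len(self.ladder):
                raise ValueError("ladder precisions must be strictly decreasing")

    @property
    def rungs(self):
        return list(self.ladder) if self.ladder else [self.precision]


@dataclass
class ScfState:
    orbitals: OrbitalSet
    fock: np.ndarray
    energies: np.ndarray
    total_energy: float
    iteration: int
    orbital_residuals: np.ndarray
    precision: float
    molecule: Molecule = None
    history: list = field(default_factory=list)
    ledger: ScreeningLedger = None
    converged: bool = False
    kinetic: np.ndarray = None
    vnuc: FunctionTree = None
    coulomb: FunctionTree = None


def _total_energy(mol, occ, T, Vn, Jm, Km):
    one = occ.sum() <= 1.0 + 1e-12
    e = float(np.sum(occ * (np.diag(T) + np.diag(Vn))))
    if not one:
        e += 0.5 * float(np.sum(occ * np.diag(Jm)))
        e -= float(np.sum(0.5 * occ * np.diag(Km)))
    return e + mol.nuclear_repulsion()


def helmholtz_update(
    state: ScfState,
    prec: float,
    vtot_phi: list | None = None,
    epsilon_floor: float = DEFAULT_EPSILON_FLOOR,
):
    """One integral-equation orbital update; returns the new (orthonormalized)
    set, per-orbital residuals, and the kinetic matrix in the new basis."""
    oset = state.orbitals
    F = state.fock
    n = len(oset)
    domain = oset.domain
    if vtot_phi is None:
        vnuc = nuclear_potential(state.molecule, domain, prec, oset.basis)
        _, _, _, vtot_phi, _, _ = _potential_matrices(oset, vnuc, prec)
    gs, news, residuals, mus = [], [], [], []
    for i in range(n):
        g = vtot_phi[i]
        for j in range(n):
            if j != i and abs(F[i, j]) > 1e-12:
                g = add(g, oset.orbitals[j], 1.0, -F[i, j])
        mu = helmholtz_mu(F[i, i], epsilon_floor)
        knl = bsh_kernel(mu, domain, prec)
        phi_new = conv_apply(knl, g, OP_FACTOR * prec).scale(-2.0)
        nn = phi_new.norm()
        if not math.isfinite(nn) or nn == 0.0:
            raise ScfError(f"non-finite Helmholtz update for orbital {i}")
        diff = add(phi_new, oset.orbitals[i], 1.0, -1.0)
        residuals.append(diff.norm())
        gs.append(g)
        news.append(phi_new)
        mus.append(mu)
    new_set = OrbitalSet(news, oset.occupations.copy(), list(oset.labels))
    gset = OrbitalSet(gs, oset.occupations.copy())
    # kinetic identity: (T - eps_j) phi~_j = -g_j
    Sng = matrix_elements_blocked(new_set, gset)
    Snn = matrix_elements_blocked(new_set, new_set)
    Tnew = -Sng + Snn * np.diag(F)[None, :]
    Tnew = 0.5 * (Tnew + Tnew.T)
    L = lowdin_matrix(Snn)
    ortho = rotate(new_set, L, OP_FACTOR * prec)
    Tortho = L @ Tnew @ L.T
    return ortho, np.array(residuals), Tortho


def scf_solve(mol: Molecule, config: ScfConfig | None = None, callback=None) -> ScfState:
    """Run the SCF to convergence, optionally along a precision ladder.

    Each rung reuses the previous rung's orbitals directly (a
    multiwavelet function built at one precision is a valid -- just
    coarser -- representation at any other).
    """
    config = config or ScfConfig()
    basis = build_basis(config.order)
    domain = default_domain(mol, config.box_padding)
    for _, _, pos in mol.atoms:
        if not domain.contains(pos):
            raise ScfError(f"atom at {pos} outside computational domain")
    ledger = ScreeningLedger()
    history = []
    oset, Tmat = _initial_guess(mol, config.rungs[0], basis, domain)
    state = None
    for rung in config.rungs:
        thr = (
            config.residual_threshold
            if config.residual_threshold is not None
            else 10.0 * rung
        )
        vnuc = nuclear_potential(mol, domain, rung, basis)
        last_e = None
        residuals = np.full(len(oset), np.inf)
        for it in range(config.max_iter):
            cache: dict = {}
            Vn, Jm, Km, vtot_phi, J, _ = _potential_matrices(
                oset, vnuc, rung, ledger, config.screening, cache
            )
            F = Tmat + Vn + Jm - Km
            F = 0.5 * (F + F.T)
            e_tot = _total_energy(mol, oset.occupations, Tmat, Vn, Jm, Km)
            state = ScfState(
                orbitals=oset,
                fock=F,
                energies=np.diag(F).copy(),
                total_energy=e_tot,
                iteration=len(history),
                orbital_residuals=residuals.copy(),
                precision=rung,
                molecule=mol,
                history=history,
                ledger=ledger,
                kinetic=Tmat,
                vnuc=vnuc,
                coulomb=J,
            )
            history.append(
                {
                    "rung": rung,
                    "iteration": len(history),
                    "energy": e_tot,
                    "max_residual": float(np.max(residuals))
                    if np.all(np.isfinite(residuals))
                    else None,
                    "orbital_energies": np.diag(F).tolist(),
                }
            )
            if callback is not None:
                callback(state)
            de = None if last_e is None else abs(e_tot - last_e)
            if (
                np.all(np.isfinite(residuals))
                and float(np.max(residuals)) <= thr
                and de is not None
                and de <= max(10.0 * thr * thr, 1e-12)
            ):
                state.converged = True
                break
            last_e = e_tot
            if config.localize and len(oset) > 1:
                loc = localize_foster_boys(oset, tol=rung, prec=rung)
                oset = loc.orbitals
                Tmat = loc.unitary @ Tmat @ loc.unitary.T
                # potentials were computed for the unlocalized set
                Vn2, Jm2, Km2, vtot_phi, _, _ = _potential_matrices(
                    oset, vnuc, rung, ledger, config.screening, {}
                )
                F = Tmat + Vn2 + Jm2 - Km2
                F = 0.5 * (F + F.T)
                state.orbitals = oset
                state.fock = F
            oset, residuals, Tmat = helmholtz_update(
                state, rung, vtot_phi=vtot_phi, epsilon_floor=config.epsilon_floor
            )
        else:
            trace = [h["max_residual"] for h in history if h["rung"] == rung]
            raise ScfError(
                f"SCF did not converge in {config.max_iter} iterations at "
                f"precision {rung}; residual trace: {trace}"
            )
    return state
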
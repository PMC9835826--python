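"""Integral-equation Hartree-Fock: guess, potentials, exchange, updates, SCF."""

import math

import numpy as np
import pytest
from scipy.special import erf

from conftest import gaussian
from mwhf.algebra import OrbitalSet, add, inner_product, matrix_elements_blocked, multiply
from mwhf.basis import build_basis
from mwhf.kernels import fit_kernel
from mwhf.convolution import apply as conv_apply
from mwhf.scf import (
    Molecule,
    ScfConfig,
    ScfState,
    coulomb_potential,
    default_domain,
    density,
    exchange_apply,
    fock_matrix,
    helmholtz_update,
    initial_guess,
    localize_foster_boys,
    nuclear_potential,
    orthonormalize,
    scf_solve,
    smoothing_length,
    _kinetic_heat,
)
from mwhf.screening import ScreeningLedger
from mwhf.tree import Domain, project


class TestInitialGuess:
    def test_hydrogen_guess_is_normalized_single_orbital(self):
        mol = Molecule.from_symbols(["H"], [np.zeros(3)])
        oset = initial_guess(mol, 1e-4)
        assert len(oset) == 1
        assert inner_product(oset[0], oset[0]) == pytest.approx(1.0, abs=1e-4)
        assert oset.occupations[0] == 1.0

    def test_helium_guess_single_doubly_occupied(self):
        mol = Molecule.from_symbols(["He"], [np.zeros(3)])
        oset = initial_guess(mol, 1e-4)
        assert len(oset) == 1
        assert inner_product(oset[0], oset[0]) == pytest.approx(1.0, abs=1e-4)
        assert oset.occupations[0] == 2.0

    def test_h2_guess_symmetric_under_atom_swap(self):
        prec = 1e-4
        mol = Molecule.from_symbols(
            ["H", "H"], [np.array([0, 0, -0.7]), np.array([0, 0, 0.7])]
        )
        oset = initial_guess(mol, prec)
        assert len(oset) == 1
        phi = oset[0]
        for pt in ([0.3, 0.1, 0.9], [0, 0, 0.7], [1.0, -1.0, 0.4]):
            mirror = [pt[0], pt[1], -pt[2]]
            assert abs(phi.evaluate(pt) - phi.evaluate(mirror)) <= 10 * prec

    def test_insufficient_guess_functions(self):
        # a bare proton chain with charge forcing more orbitals than functions
        mol = Molecule.from_symbols(
            ["H", "H"], [np.array([0, 0, -0.7]), np.array([0, 0, 0.7])], charge=-4
        )
        with pytest.raises(Exception, match="guess"):
            initial_guess(mol, 1e-3)


class TestCoulomb:
    def test_hydrogen_gaussian_density_matches_erf_potential(self):
        prec = 1e-4
        mol = Molecule.from_symbols(["H"], [np.zeros(3)])
        oset = initial_guess(mol, 0.1 * prec)
        J = coulomb_potential(oset, prec)
        alpha = 8.0 / (9.0 * math.pi)  # the guess exponent; density ~ e^{-2 alpha r^2}
        a2 = 2.0 * alpha
        for r in (0.0, 1.0, 3.0, 6.0):
            exact = (
                2.0 * math.sqrt(a2 / math.pi)
                if r == 0
                else erf(math.sqrt(a2) * r) / r
            )
            assert J.evaluate([r, 0, 0]) == pytest.approx(exact, abs=10 * prec)

    def test_helium_charge_conservation(self):
        mol = Molecule.from_symbols(["He"], [np.zeros(3)])
        oset = initial_guess(mol, 1e-5)
        rho = density(oset, 1e-5)
        assert rho.integral() == pytest.approx(2.0, abs=1e-4)

    def test_doubling_occupations_doubles_the_potential(self):
        prec = 1e-4
        mol = Molecule.from_symbols(["He"], [np.zeros(3)])
        oset = initial_guess(mol, prec)
        J1 = coulomb_potential(oset, prec)
        double = OrbitalSet(
            [t.copy() for t in oset.orbitals], 2.0 * oset.occupations
        )
        J2 = coulomb_potential(double, prec)
        for pt in ([0, 0, 0], [2.0, 0, 0], [0, -4.0, 1.0]):
            assert J2.evaluate(pt) == pytest.approx(
                2.0 * J1.evaluate(pt), abs=20 * prec
            )


@pytest.fixture(scope="module")
def localized_triplet():
    """Three orthonormalized localized orbitals in one box."""
    basis = build_basis(5)
    dom = Domain(np.zeros(3), 24.0)
    centers = [(-3.0, 0, 0), (0.0, 2.0, 0), (3.0, -1.0, 0)]
    trees = [
        project(gaussian(alpha=1.2, center=c), dom, 1e-5, basis) for c in centers
    ]
    return orthonormalize(OrbitalSet(trees, np.full(3, 2.0)), 1e-6)


class TestExchange:
    def test_single_orbital_self_exchange_is_half_coulomb(self):
        prec = 1e-4
        mol = Molecule.from_symbols(["He"], [np.zeros(3)])
        oset = initial_guess(mol, 0.1 * prec)
        J = coulomb_potential(oset, prec)  # density 2 |phi|^2
        K = exchange_apply(oset, 0, prec)
        jj = inner_product(oset[0], multiply(J, oset[0], prec))
        kk = inner_product(oset[0], K)
        assert kk == pytest.approx(jj / 2.0, abs=20 * prec)

    def test_exchange_matrix_hermitian_and_screening_sound(self, localized_triplet):
        prec = 1e-4
        oset = localized_triplet
        led = ScreeningLedger()
        k_scr = [exchange_apply(oset, i, prec, led, True) for i in range(3)]
        led.check()
        K_scr = matrix_elements_blocked(oset, OrbitalSet(k_scr, oset.occupations))
        assert np.max(np.abs(K_scr - K_scr.T)) <= 10 * prec
        k_ref = [exchange_apply(oset, i, prec, None, False) for i in range(3)]
        K_ref = matrix_elements_blocked(oset, OrbitalSet(k_ref, oset.occupations))
        assert np.allclose(K_scr, K_ref, atol=10 * prec)

    def test_distant_pair_is_neglected_and_harmless(self):
        prec = 1e-4
        basis = build_basis(5)
        dom = Domain(np.zeros(3), 46.0)
        a = project(gaussian(center=(-15.0, 0, 0)), dom, 1e-5, basis)
        b = project(gaussian(center=(15.0, 0, 0)), dom, 1e-5, basis)
        oset = orthonormalize(OrbitalSet([a, b], np.full(2, 2.0)), 1e-6)
        led = ScreeningLedger()
        k_scr = [exchange_apply(oset, i, prec, led, True) for i in range(2)]
        led.check()
        assert led.exchange_pairs_total == 1
        assert led.exchange_pairs_neglected == 1
        k_ref = [exchange_apply(oset, i, prec, None, False) for i in range(2)]
        for i in range(2):
            e_scr = inner_product(oset[i], k_scr[i])
            e_ref = inner_product(oset[i], k_ref[i])
            assert abs(e_scr - e_ref) <= 1e-4


class TestFockMatrix:
    def test_converged_hydrogen_diagonal_is_minus_half(self, h_scf_state):
        prec = h_scf_state.precision
        assert h_scf_state.fock[0, 0] == pytest.approx(-0.5, abs=50 * prec)

    def test_hermiticity_on_an_iterate(self, he_scf_state):
        F = he_scf_state.fock
        assert np.max(np.abs(F - F.T)) <= 10 * he_scf_state.precision

    def test_blocked_potential_matrix_equals_loop_oracle(self, localized_triplet):
        from mwhf.algebra import matrix_elements_loop

        mol = Molecule.from_symbols(["He"], [np.zeros(3)])
        vnuc = nuclear_potential(mol, localized_triplet.domain, 1e-4, build_basis(5))
        vphi = OrbitalSet(
            [multiply(vnuc, t, 1e-5) for t in localized_triplet.orbitals],
            localized_triplet.occupations,
        )
        blocked = matrix_elements_blocked(localized_triplet, vphi)
        loop = matrix_elements_loop(localized_triplet, vphi)
        assert np.allclose(blocked, loop, atol=1e-10)

    def test_fock_matrix_standalone_on_hydrogen_guess(self):
        """The public assembly route: F_11 of the Gaussian guess is its
        variational energy, -0.424 Ha for the single-Gaussian 1s."""
        mol = Molecule.from_symbols(["H"], [np.zeros(3)])
        oset = initial_guess(mol, 1e-4)
        F = fock_matrix(oset, mol, 1e-4)
        assert F.shape == (1, 1)
        # <T> = 3a/2, <V> = -2 sqrt(2a/pi) at a = 8/(9 pi)
        a = 8.0 / (9.0 * math.pi)
        expected = 1.5 * a - 2.0 * math.sqrt(2.0 * a / math.pi)
        assert F[0, 0] == pytest.approx(expected, abs=5e-3)

    def test_heat_kernel_kinetic_route(self):
        """Gradient-free kinetic of a normalized Gaussian: <T> = 3 alpha / 2."""
        alpha = 0.5
        basis = build_basis(5)
        dom = Domain(np.zeros(3), 16.0)
        amp = (2.0 * alpha / math.pi) ** 0.75
        t = project(gaussian(alpha=alpha, amplitude=amp), dom, 1e-6, basis)
        oset = OrbitalSet([t], np.array([1.0]))
        T = _kinetic_heat(oset, 1e-5)
        assert T[0, 0] == pytest.approx(1.5 * alpha, rel=2e-3)


class TestHelmholtzUpdate:
    def test_exact_hydrogen_is_a_fixed_point(self):
        """-2 G_1 * (V phi_1s) reproduces phi_1s to operator accuracy."""
        prec = 1e-4
        basis = build_basis(5)
        mol = Molecule.from_symbols(["H"], [np.zeros(3)])
        dom = Domain(np.zeros(3), 32.0)

        def phi1s(p):
            r = np.sqrt(np.sum(p**2, axis=-1))
            return np.exp(-r) / math.sqrt(math.pi)

        phi = project(phi1s, dom, prec, basis)
        V = nuclear_potential(mol, dom, prec, basis)
        Vphi = multiply(V, phi, 0.2 * prec)
        G = fit_kernel(1.0, 1e-4, 30.0, prec)
        new = conv_apply(G, Vphi, 0.2 * prec).scale(-2.0)
        res = add(new, phi, 1.0, -1.0)
        assert res.norm() <= 50 * prec
        # the orbital energy recovered from <phi|V|phi> + <phi|T|phi> ~ -0.5
        assert inner_product(phi, Vphi) == pytest.approx(-1.0, abs=10 * prec)

    def test_helium_residuals_decrease_initially(self, he_scf_state):
        res = [
            h["max_residual"]
            for h in he_scf_state.history
            if h["max_residual"] is not None
        ]
        assert all(r1 < r0 for r0, r1 in zip(res[:5], res[1:6]))

    def test_energy_tail_is_monotone_to_tolerance(self, he_scf_state):
        prec = he_scf_state.precision
        es = [h["energy"] for h in he_scf_state.history][-3:]
        for e0, e1 in zip(es, es[1:]):
            assert e1 <= e0 + 10 * prec

    def test_diagonal_fock_makes_coupling_immaterial(self, h_scf_state):
        """With canonical (diagonal-F) orbitals the coupling sum vanishes."""
        prec = h_scf_state.precision
        st = h_scf_state
        new1, res1, _ = helmholtz_update(st, prec)
        F2 = st.fock.copy()
        state2 = ScfState(
            orbitals=st.orbitals, fock=F2, energies=st.energies,
            total_energy=st.total_energy, iteration=st.iteration,
            orbital_residuals=st.orbital_residuals, precision=prec,
            molecule=st.molecule,
        )
        new2, res2, _ = helmholtz_update(state2, prec)
        diff = add(new1[0], new2[0], 1.0, -1.0)
        assert diff.norm() <= 10 * prec


class TestOrthonormalize:
    def test_already_orthonormal_set_is_fixed(self, localized_triplet):
        again = orthonormalize(localized_triplet, 1e-6)
        for t_old, t_new in zip(localized_triplet.orbitals, again.orbitals):
            d = add(t_old, t_new, 1.0, -1.0)
            assert d.norm() <= 1e-5

    def test_overlapping_pair_gram_becomes_identity(self):
        basis = build_basis(5)
        dom = Domain(np.zeros(3), 20.0)
        # two unit-norm Gaussians with overlap exp(-d^2/2) = 0.5
        d = math.sqrt(2.0 * math.log(2.0))
        amp = (2.0 / math.pi) ** 0.75
        a = project(gaussian(amplitude=amp, center=(-d / 2, 0, 0)), dom, 1e-8, basis)
        b = project(gaussian(amplitude=amp, center=(d / 2, 0, 0)), dom, 1e-8, basis)
        oset = OrbitalSet([a, b], np.full(2, 2.0))
        S = matrix_elements_blocked(oset, oset)
        assert S[0, 1] == pytest.approx(0.5, abs=1e-6)
        ortho = orthonormalize(oset, 1e-9)
        G = matrix_elements_blocked(ortho, ortho)
        assert np.allclose(G, np.eye(2), atol=1e-8)
        # span preserved: old orbitals reproduced by their projection onto the new set
        M = matrix_elements_blocked(ortho, oset)  # <new_i | old_j>
        for j in range(2):
            recon = add(ortho[0], ortho[1], M[0, j], M[1, j])
            resid = add(recon, oset[j], 1.0, -1.0)
            assert resid.norm() <= 1e-7

    def test_singular_gram_is_rejected(self, gauss_tree):
        oset = OrbitalSet([gauss_tree, gauss_tree.copy()], np.full(2, 2.0))
        with pytest.raises(Exception, match="positive definite|eigenvalue"):
            orthonormalize(oset, 1e-6)


@pytest.fixture(scope="module")
def mixed_pair():
    """Two distant 1s-like orbitals, atom-centered and as +/- combinations."""
    basis = build_basis(5)
    dom = Domain(np.zeros(3), 32.0)
    amp = (2.0 / math.pi) ** 0.75
    a = project(gaussian(amplitude=amp, center=(-5.0, 0, 0)), dom, 1e-7, basis)
    b = project(gaussian(amplitude=amp, center=(5.0, 0, 0)), dom, 1e-7, basis)
    plus = add(a, b, 1 / math.sqrt(2), 1 / math.sqrt(2))
    minus = add(a, b, 1 / math.sqrt(2), -1 / math.sqrt(2))
    return (
        OrbitalSet([a, b], np.full(2, 2.0)),
        OrbitalSet([plus, minus], np.full(2, 2.0)),
    )


class TestFosterBoys:
    def test_rotation_recovers_atom_centered_orbitals(self, mixed_pair):
        atom_centered, mixed = mixed_pair
        from mwhf.scf import dipole_matrices

        res = localize_foster_boys(mixed, tol=1e-10, prec=1e-8)
        assert res.converged
        X_loc = dipole_matrices(res.orbitals)
        X_ref = dipole_matrices(atom_centered)
        obj_loc = sum(float(np.sum(np.diag(x) ** 2)) for x in X_loc)
        obj_ref = sum(float(np.sum(np.diag(x) ** 2)) for x in X_ref)
        assert obj_loc == pytest.approx(obj_ref, abs=1e-6)

    def test_already_localized_set_keeps_identity(self, mixed_pair):
        atom_centered, _ = mixed_pair
        res = localize_foster_boys(atom_centered, tol=1e-8)
        assert np.allclose(np.abs(res.unitary), np.eye(2), atol=1e-8)

    def test_unitary_mixing_leaves_energies_invariant(self, mixed_pair):
        """Coulomb and exchange energies are invariant under the unitary
        relating localized and delocalized orbitals (within operator accuracy)."""
        prec = 1e-4
        atom_centered, mixed = mixed_pair
        rho_a = density(atom_centered, 0.1 * prec)
        rho_m = density(mixed, 0.1 * prec)
        assert rho_a.integral() == pytest.approx(rho_m.integral(), abs=prec)
        ex = {}
        for name, oset in (("loc", atom_centered), ("mix", mixed)):
            ks = [exchange_apply(oset, i, prec) for i in range(2)]
            ex[name] = sum(inner_product(oset[i], ks[i]) for i in range(2))
        assert ex["loc"] == pytest.approx(ex["mix"], abs=10 * prec)

    def test_objective_never_decreases(self, mixed_pair):
        _, mixed = mixed_pair
        from mwhf.scf import dipole_matrices

        X0 = dipole_matrices(mixed)
        obj0 = sum(float(np.sum(np.diag(x) ** 2)) for x in X0)
        res = localize_foster_boys(mixed, tol=1e-10, prec=1e-8)
        assert res.objective >= obj0 - 1e-12


class TestScfSolve:
    def test_hydrogen_total_energy(self, h_scf_state):
        assert h_scf_state.converged
        assert h_scf_state.total_energy == pytest.approx(-0.5, abs=5e-4)

    def test_helium_total_energy_vs_reference(self, he_scf_state, he_hf_reference):
        """He energy agrees with an independent large-basis HF oracle."""
        assert he_scf_state.converged
        assert he_hf_reference == pytest.approx(-2.86168, abs=2e-4)  # oracle sanity
        assert he_scf_state.total_energy == pytest.approx(he_hf_reference, abs=5e-3)

    def test_kinetic_route_agrees_with_virial_on_hydrogen(self, h_scf_state):
        # at the exact solution E = -T, so T = +0.5
        assert h_scf_state.kinetic[0, 0] == pytest.approx(0.5, abs=1e-3)

    def test_precision_ladder_reuses_coarse_solution(self, h_scf_state):
        mol = Molecule.from_symbols(["H"], [np.zeros(3)])
        ladder_state = scf_solve(
            mol, ScfConfig(precision=1e-4, ladder=[1e-3, 1e-4], max_iter=25)
        )
        assert ladder_state.total_energy == pytest.approx(
            h_scf_state.total_energy, abs=1e-4
        )
        tight_iters = [
            h for h in ladder_state.history if h["rung"] == 1e-4
        ]
        direct_iters = h_scf_state.history
        assert len(tight_iters) < len(direct_iters)

    def test_smoothing_length_shrinks_with_charge_and_precision(self):
        assert smoothing_length(2, 1e-4) == smoothing_length(1, 1e-4) / 2
        assert smoothing_length(1, 1e-6) <= smoothing_length(1, 1e-4)

    def test_odd_many_electron_molecule_rejected(self):
        with pytest.raises(ValueError, match="even electron count"):
            Molecule.from_symbols(["Li"], [np.zeros(3)])
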
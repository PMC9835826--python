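"""Tree arithmetic, inner products, node-blocked matrices, rotations, local views."""

import numpy as np
import pytest

from conftest import gaussian, random_gaussian_mix_tree
from mwhf.algebra import (
    OrbitalSet,
    add,
    from_local_view,
    inner_product,
    matrix_elements_blocked,
    matrix_elements_loop,
    multiply,
    rotate,
    to_local_view,
)
from mwhf.scf import orthonormalize
from mwhf.screening import ScreeningLedger
from mwhf.tree import Domain, project


@pytest.fixture(scope="module")
def random_set(basis5, unit_domain16, rng):
    trees = [
        random_gaussian_mix_tree(rng, basis5, unit_domain16, prec=1e-4)
        for _ in range(4)
    ]
    return OrbitalSet(trees, np.full(4, 2.0))


class TestAdd:
    def test_self_cancellation(self, gauss_tree):
        z = add(gauss_tree, gauss_tree, 1.0, -1.0, prec=1e-8)
        assert z.norm() <= 1e-8

    def test_add_zero_tree_scales(self, basis5, unit_domain16, gauss_tree):
        from mwhf.tree import FunctionTree

        zero = FunctionTree(basis5, unit_domain16)
        two = add(gauss_tree, zero, 2.0, 1.0)
        assert two.norm() == pytest.approx(2.0 * gauss_tree.norm(), rel=1e-12)
        for idx, nd in gauss_tree.nodes.items():
            assert np.allclose(two.nodes[idx].s, 2.0 * nd.s, atol=1e-12)

    def test_integral_is_additive_for_offset_gaussians(self, basis5):
        dom = Domain(np.zeros(3), 20.0)
        a = project(gaussian(center=(-2.5, 0, 0)), dom, 1e-6, basis5)
        b = project(gaussian(alpha=1.7, center=(2.5, 1.0, 0)), dom, 1e-6, basis5)
        s = add(a, b, 1.0, 1.0)
        assert s.integral() == pytest.approx(a.integral() + b.integral(), rel=1e-10)

    def test_mismatched_domains_rejected(self, basis5, gauss_tree):
        other = project(gaussian(), Domain(np.zeros(3), 8.0), 1e-4, basis5)
        with pytest.raises(ValueError, match="domain"):
            add(gauss_tree, other)


class TestMultiply:
    def test_gaussian_square_integral(self, basis5, unit_domain16):
        alpha = 1.0
        t = project(gaussian(alpha=alpha), unit_domain16, 1e-6, basis5)
        sq = multiply(t, t, 1e-6)
        assert sq.integral() == pytest.approx(
            (np.pi / (2 * alpha)) ** 1.5, rel=1e-5
        )

    def test_multiply_by_constant_one_is_identity(self, basis5, unit_domain16, gauss_tree):
        one = project(lambda p: np.ones(p.shape[:-1]), unit_domain16, 1e-6, basis5)
        prod = multiply(gauss_tree, one, 1e-5)
        assert abs(prod.norm() - gauss_tree.norm()) <= 1e-5 * gauss_tree.norm()
        assert prod.evaluate([0.7, -0.3, 0.2]) == pytest.approx(
            gauss_tree.evaluate([0.7, -0.3, 0.2]), abs=1e-4
        )

    def test_distant_factors_give_cheap_near_zero_product(self, basis5):
        dom = Domain(np.zeros(3), 36.0)
        a = project(gaussian(center=(-10, 0, 0)), dom, 1e-5, basis5)
        b = project(gaussian(center=(10, 0, 0)), dom, 1e-5, basis5)
        prod = multiply(a, b, 1e-5)
        assert prod.norm() <= 1e-5
        assert len(prod) <= min(len(a), len(b))


class TestInnerProduct:
    def test_self_inner_product_is_norm_squared(self, gauss_tree):
        assert inner_product(gauss_tree, gauss_tree) == pytest.approx(
            gauss_tree.norm_sq(), rel=1e-12
        )

    def test_gaussian_overlap_closed_form(self, basis5):
        dom = Domain(np.zeros(3), 24.0)
        A, B = np.array([-1.0, 0, 0.5]), np.array([1.5, 0.3, 0])
        a = project(gaussian(center=A), dom, 1e-6, basis5)
        b = project(gaussian(center=B), dom, 1e-6, basis5)
        exact = (np.pi / 2) ** 1.5 * np.exp(-np.sum((A - B) ** 2) / 2.0)
        assert inner_product(a, b) == pytest.approx(exact, abs=10 * 1e-6)

    def test_symmetry_and_bilinearity(self, basis5, unit_domain16, rng):
        a = random_gaussian_mix_tree(rng, basis5, unit_domain16)
        b = random_gaussian_mix_tree(rng, basis5, unit_domain16)
        c = random_gaussian_mix_tree(rng, basis5, unit_domain16)
        assert inner_product(a, b) == pytest.approx(inner_product(b, a), rel=1e-12)
        s = add(b, c, 2.0, -0.5)
        assert inner_product(a, s) == pytest.approx(
            2.0 * inner_product(a, b) - 0.5 * inner_product(a, c), rel=1e-10
        )
        # Cauchy-Schwarz
        assert abs(inner_product(a, b)) <= a.norm() * b.norm() * (1 + 1e-12)


class TestBlockedMatrixElements:
    def test_orthonormal_set_gives_identity(self, random_set):
        prec = 1e-4
        oset = orthonormalize(random_set, 0.1 * prec)
        G = matrix_elements_blocked(oset, oset)
        assert np.allclose(G, np.eye(len(oset)), atol=10 * prec)

    def test_blocked_equals_nested_loop_oracle(self, random_set):
        M = matrix_elements_blocked(random_set, random_set)
        L = matrix_elements_loop(random_set, random_set)
        assert np.allclose(M, L, atol=1e-12)

    def test_node_screening_skips_blocks_but_not_values(self, basis5):
        dom = Domain(np.zeros(3), 40.0)
        left = [
            project(gaussian(alpha=al, center=(-12, 0, 0)), dom, 1e-5, basis5)
            for al in (1.0, 1.5)
        ]
        right = [
            project(gaussian(alpha=al, center=(12, 0, 0)), dom, 1e-5, basis5)
            for al in (1.0, 1.5)
        ]
        oset = OrbitalSet(left + right, np.full(4, 2.0))
        led = ScreeningLedger()
        M = matrix_elements_blocked(oset, oset, ledger=led)
        led.check()
        assert led.blocks_skipped > 0  # off-cluster blocks never touched
        M_noscreen = matrix_elements_blocked(oset, oset, screen=False)
        assert np.allclose(M, M_noscreen, atol=1e-12)
        assert np.allclose(M, matrix_elements_loop(oset, oset), atol=1e-12)


class TestRotate:
    def test_identity_rotation_preserves_coefficients(self, random_set):
        out = rotate(random_set, np.eye(len(random_set)), 1e-12)
        for t_old, t_new in zip(random_set.orbitals, out.orbitals):
            for idx, nd in t_old.nodes.items():
                assert np.allclose(t_new.nodes[idx].s, nd.s, atol=1e-12)

    def test_unitary_rotation_preserves_gram(self, random_set, rng):
        n = len(random_set)
        Q, _ = np.linalg.qr(rng.standard_normal((n, n)))
        prec = 1e-5
        out = rotate(random_set, Q, 0.1 * prec)
        G0 = matrix_elements_blocked(random_set, random_set)
        G1 = matrix_elements_blocked(out, out)
        assert np.allclose(G1, Q @ G0 @ Q.T, atol=10 * prec)

    def test_givens_rotation_matches_add_oracle(self, basis5):
        dom = Domain(np.zeros(3), 24.0)
        a = project(gaussian(center=(-2, 0, 0)), dom, 1e-7, basis5)
        b = project(gaussian(center=(2, 0, 0)), dom, 1e-7, basis5)
        oset = OrbitalSet([a, b], np.full(2, 2.0))
        th = 0.3
        A = np.array([[np.cos(th), np.sin(th)], [-np.sin(th), np.cos(th)]])
        out = rotate(oset, A, 1e-12)
        oracle0 = add(a, b, np.cos(th), np.sin(th))
        diff = add(out.orbitals[0], oracle0, 1.0, -1.0)
        assert diff.norm() <= 1e-10

    def test_dimension_mismatch(self, random_set):
        with pytest.raises(ValueError, match="shape"):
            rotate(random_set, np.eye(3), 1e-6)


class TestLocalView:
    def test_round_trip_is_coefficient_identical(self, random_set):
        view = to_local_view(random_set)
        back = from_local_view(view)
        for t_old, t_new in zip(random_set.orbitals, back.orbitals):
            assert set(t_old.nodes) == set(t_new.nodes)
            for idx, nd in t_old.nodes.items():
                assert np.array_equal(t_new.nodes[idx].s, nd.s)
                if nd.d is None:
                    assert t_new.nodes[idx].d is None
                else:
                    assert np.array_equal(t_new.nodes[idx].d, nd.d)

    def test_disjoint_orbitals_have_single_contributors_at_depth(self, basis5):
        dom = Domain(np.zeros(3), 48.0)
        trees = [
            project(gaussian(center=(c, 0, 0)), dom, 1e-4, basis5)
            for c in (-15.0, 0.0, 15.0)
        ]
        view = to_local_view(OrbitalSet(trees, np.full(3, 2.0)))
        deep = [e for idx, e in view.entries.items() if idx[0] >= 3]
        assert deep and all(len(ids) == 1 for ids, _ in deep)

    def test_chain_contributor_count_saturates(self, basis5):
        """Contributors per fixed-size box stay O(1) as a localized chain grows.

        The domain grows with the chain, so counts are compared on boxes
        of fixed physical size (about one site spacing).
        """
        import math

        from mwhf.synthetic import gaussian_chain_set

        maxc = {}
        for n in (4, 8, 16):
            oset = gaussian_chain_set(n, spacing=3.0, prec=1e-3, order=5)
            smin = math.ceil(math.log2(oset.domain.edge / 3.0))
            view = to_local_view(oset)
            maxc[n] = max(
                len(ids) for idx, (ids, _) in view.entries.items() if idx[0] >= smin
            )
        # saturation: doubling the chain again adds no contributors
        assert maxc[16] <= maxc[8]
        assert maxc[16] <= 4
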
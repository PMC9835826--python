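"""Multiwavelet bases on the unit interval and their two-scale filters.

The scaling space at order ``k`` on a dyadic box is spanned by ``k + 1``
orthonormal polynomials per direction.  Two families are provided:

* ``legendre`` -- normalized shifted Legendre polynomials
  ``phi_j(x) = sqrt(2 j + 1) P_j(2 x - 1)`` on ``[0, 1]``; polynomial
  reproduction (vanishing wavelet coefficients on polynomial input) is
  exact for this family, which is why it is the default.
* ``interpolating`` -- normalized Lagrange cardinal functions through the
  ``k + 1`` Gauss-Legendre points of ``[0, 1]``.

The two-scale relation connects the scaling coefficients of the two
half-interval children to the scaling *and* wavelet coefficients of the
parent.  The full filter is an orthogonal ``2(k+1) x 2(k+1)`` matrix

    [ s_parent ]   [ H0  H1 ] [ s_left  ]
    [ d_parent ] = [ G0  G1 ] [ s_right ]

where the ``H`` blocks are fixed by the basis and the wavelet rows ``G``
are a deterministic orthonormal completion (Householder QR) of the
orthogonal complement of the ``H`` rows.  Any such completion spans the
same wavelet space; the completion is fixed once so that coefficient
layouts are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MultiwaveletBasis", "build_basis", "coefficients_per_node_3d"]

MAX_ORDER = 13

_BASIS_CACHE: dict[tuple[int, str], "MultiwaveletBasis"] = {}


def coefficients_per_node_3d(order: int) -> int:
    """Total number of 3D coefficients (scaling + wavelet) per node: ``(2(k+1))^3``."""
    if order < 0:
        raise ValueError("order must be non-negative")
    return (2 * (order + 1)) ** 3


def _gauss_legendre_01(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes and weights mapped to [0, 1]."""
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


class MultiwaveletBasis:
    """Orthonormal multiwavelet basis of a given polynomial order.

    Parameters
    ----------
    order : int
        Highest per-direction polynomial degree ``k`` (``1 <= k <= 13``).
    family : {"legendre", "interpolating"}
        Scaling-function family.

    Attributes
    ----------
    order : int
    n : int
        Scaling functions per direction, ``k + 1``.
    filter : ndarray, shape (2n, 2n)
        Orthogonal two-scale filter; rows ``0..n-1`` produce parent
        scaling coefficients, rows ``n..2n-1`` wavelet coefficients.
    quad_x, quad_w : ndarray
        ``2(k+1)``-point Gauss-Legendre rule on ``[0, 1]`` used for
        projection and pointwise products.
    """

    def __init__(self, order: int, family: str = "legendre"):
        if not (1 <= order <= MAX_ORDER):
            raise ValueError(
                f"unsupported multiwavelet order {order}; supported range is 1..{MAX_ORDER}"
            )
        if family not in ("legendre", "interpolating"):
            raise ValueError(f"unknown basis family {family!r}")
        self.order = int(order)
        self.family = family
        self.n = self.order + 1

        nq = 2 * self.n
        self.quad_x, self.quad_w = _gauss_legendre_01(nq)

        # interpolation nodes/weights used by the interpolating family
        self._interp_x, self._interp_w = _gauss_legendre_01(self.n)

        self.filter = self._build_filter()
        # value <-> coefficient maps at the projection quadrature
        E = self.eval_scaling(self.quad_x)          # (nq, n)
        self.values_from_coeffs = E
        self.coeffs_from_values = (self.quad_w[:, None] * E).T   # (n, nq)

        self._cc = None  # cross-correlation coefficients, built lazily

    # ------------------------------------------------------------------
    # scaling-function evaluation
    # ------------------------------------------------------------------
    def eval_scaling(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the ``k + 1`` scaling functions at points of ``[0, 1]``.

        Returns an array of shape ``x.shape + (k + 1,)``.
        """
        x = np.asarray(x, dtype=float)
        out = np.empty(x.shape + (self.n,))
        if self.family == "legendre":
            t = 2.0 * x - 1.0
            out[..., 0] = 1.0
            if self.n > 1:
                out[..., 1] = t
            for j in range(2, self.n):
                out[..., j] = (
                    (2 * j - 1) * t * out[..., j - 1] - (j - 1) * out[..., j - 2]
                ) / j
            out *= np.sqrt(2 * np.arange(self.n) + 1)
        else:
            # Lagrange cardinal functions at Gauss-Legendre nodes, L2-normalized
            xi = self._interp_x
            for j in range(self.n):
                lj = np.ones_like(x)
                for m in range(self.n):
                    if m != j:
                        lj = lj * (x - xi[m]) / (xi[j] - xi[m])
                out[..., j] = lj / np.sqrt(self._interp_w[j])
        return out

    # ------------------------------------------------------------------
    # two-scale filter
    # ------------------------------------------------------------------
    def _build_filter(self) -> np.ndarray:
        n = self.n
        nq = len(self.quad_x)
        # H0[j, i] = sqrt(2) int_0^{1/2} phi_j(x) phi_i(2x) dx
        #          = (1/sqrt(2)) int_0^1 phi_j(t/2) phi_i(t) dt
        t, w = self.quad_x, self.quad_w
        Pj_left = self.eval_scaling(0.5 * t)          # (nq, n)
        Pj_right = self.eval_scaling(0.5 * (t + 1.0))
        Pi = self.eval_scaling(t)
        H0 = (1.0 / np.sqrt(2.0)) * np.einsum("q,qj,qi->ji", w, Pj_left, Pi)
        H1 = (1.0 / np.sqrt(2.0)) * np.einsum("q,qj,qi->ji", w, Pj_right, Pi)
        H = np.hstack([H0, H1])                        # (n, 2n)

        # wavelet rows: deterministic orthonormal completion of H's row space
        Q, _ = np.linalg.qr(H.T, mode="complete")      # (2n, 2n)
        G = Q[:, n:].T
        # fix signs for reproducibility: make the largest-magnitude entry positive
        for r in range(G.shape[0]):
            lead = np.argmax(np.abs(G[r]))
            if G[r, lead] < 0:
                G[r] = -G[r]
        F = np.vstack([H, G])
        assert np.allclose(F @ F.T, np.eye(2 * n), atol=1e-12)
        return F

    # ------------------------------------------------------------------
    # cross-correlation polynomials (used by convolution operators)
    # ------------------------------------------------------------------
    def cross_correlation(self) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise-polynomial cross-correlations of scaling functions.

        ``C_pq(z) = int phi_p(x) phi_q(x - z) dx`` is a polynomial of
        degree ``<= 2k + 1`` on each of ``[-1, 0]`` and ``[0, 1]``.
        Returns ``(c_neg, c_pos)``, each of shape ``(n, n, 2k + 2)``,
        holding monomial coefficients in ``z`` (ascending order).
        """
        if self._cc is not None:
            return self._cc
        n, k = self.n, self.order
        deg = 2 * k + 1
        npts = deg + 1
        # sample points per branch (Chebyshev to keep the Vandermonde solve tame)
        zs_pos = 0.5 * (1.0 - np.cos(np.pi * (np.arange(npts) + 0.5) / npts))
        zs_neg = -zs_pos
        gq_x, gq_w = _gauss_legendre_01(2 * n + 2)

        def cmat(z: float) -> np.ndarray:
            # C_pq(z) with integration over the overlap of [0,1] and [z, 1+z]
            lo, hi = max(0.0, z), min(1.0, 1.0 + z)
            if hi <= lo:
                return np.zeros((n, n))
            x = lo + (hi - lo) * gq_x
            w = (hi - lo) * gq_w
            Pp = self.eval_scaling(x)
            Pq = self.eval_scaling(x - z)
            return np.einsum("q,qp,qr->pr", w, Pp, Pq)

        def fit(zs: np.ndarray) -> np.ndarray:
            V = np.vander(zs, npts, increasing=True)
            samples = np.stack([cmat(z) for z in zs])       # (npts, n, n)
            coef = np.linalg.solve(V, samples.reshape(npts, -1))
            return coef.T.reshape(n, n, npts)

        self._cc = (fit(zs_neg), fit(zs_pos))
        return self._cc

    def __repr__(self) -> str:  # pragma: no cover
        return f"MultiwaveletBasis(order={self.order}, family={self.family!r})"


def build_basis(order: int, family: str = "legendre") -> MultiwaveletBasis:
    """Return a (cached) multiwavelet basis of the given order and family."""
    key = (int(order), family)
    if key not in _BASIS_CACHE:
        _BASIS_CACHE[key] = MultiwaveletBasis(order, family)
    return _BASIS_CACHE[key]
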
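"""Adaptive multiwavelet function trees on a cubic domain.

A :class:`FunctionTree` represents a real scalar function of three
variables as a complete octree of dyadic boxes.  A box at scale ``s``
and translation ``l`` carries ``(k+1)^3`` scaling coefficients; refined
(non-leaf) boxes additionally carry ``7 (k+1)^3`` wavelet coefficients
holding the detail lost when coarsening from the eight children.  The
basis functions are orthonormal under the physical L2 inner product, so
the squared norm of the function is the squared Euclidean norm of the
root scaling block plus all wavelet blocks (Parseval).

Coefficient layout: a full per-node block has shape ``(2n, 2n, 2n)``
with ``n = k + 1``; axes are ordered x, y, z and the per-direction
polynomial index varies fastest in z, then y, then x (C order).  The
leading ``n x n x n`` octant of a block is the scaling part, the seven
remaining octants are the wavelet part.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .basis import MultiwaveletBasis, build_basis

__all__ = [
    "Domain",
    "FunctionNode",
    "FunctionTree",
    "project",
    "mw_transform",
    "truncate",
    "evaluate",
    "refinement_threshold",
]

ROOT = (0, 0, 0, 0)
DEFAULT_MAX_SCALE = 20

NodeIndex = tuple  # (scale, lx, ly, lz)


def node_children(idx: NodeIndex):
    """The eight child indices of ``(s, l)``: ``(s + 1, 2 l + b)``, ``b in {0,1}^3``."""
    s, lx, ly, lz = idx
    return [
        (s + 1, 2 * lx + bx, 2 * ly + by, 2 * lz + bz)
        for bx in (0, 1)
        for by in (0, 1)
        for bz in (0, 1)
    ]


def node_parent(idx: NodeIndex) -> NodeIndex:
    s, lx, ly, lz = idx
    return (s - 1, lx // 2, ly // 2, lz // 2)


def refinement_threshold(prec: float, fnorm: float) -> float:
    """Scale-independent refinement rule: refine while ``|d| > prec * max(|f|, 1)``."""
    return prec * max(fnorm, 1.0)


@dataclass
class Domain:
    """Axis-aligned cubic domain (atomic units)."""

    center: np.ndarray
    edge: float

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.edge <= 0:
            raise ValueError("domain edge must be positive")

    @property
    def corner(self) -> np.ndarray:
        return self.center - 0.5 * self.edge

    def to_unit(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, dtype=float) - self.corner) / self.edge

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        return self.corner + self.edge * np.asarray(u, dtype=float)

    def contains(self, pt) -> bool:
        u = self.to_unit(pt)
        return bool(np.all(u >= 0.0) and np.all(u <= 1.0))

    def same_as(self, other: "Domain") -> bool:
        return np.allclose(self.center, other.center) and np.isclose(
            self.edge, other.edge
        )


@dataclass
class FunctionNode:
    """One octree box: scaling block, optional wavelet block, leaf flag."""

    s: np.ndarray  # (n, n, n) scaling coefficients
    d: np.ndarray | None = None  # (2n, 2n, 2n) wavelet block (scaling octant zero)

    @property
    def is_leaf(self) -> bool:
        return self.d is None

    def wavelet_norm(self) -> float:
        return 0.0 if self.d is None else float(np.sqrt(np.sum(self.d * self.d)))


def _apply3(M: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Apply matrix ``M`` along each of the three (equal-length) axes of ``T``."""
    m, b = M.shape
    T = (M @ T.reshape(b, -1)).reshape(m, b, b)
    T = (T.transpose(0, 2, 1).reshape(m * b, b) @ M.T).reshape(m, b, m)
    T = T.transpose(0, 2, 1)
    T = (T.reshape(m * m, b) @ M.T).reshape(m, m, m)
    return T


class FunctionTree:
    """Adaptive multiwavelet representation of a 3D scalar function."""

    def __init__(
        self,
        basis: MultiwaveletBasis,
        domain: Domain,
        prec: float = 0.0,
        max_scale: int = DEFAULT_MAX_SCALE,
    ):
        self.basis = basis
        self.domain = domain
        self.prec = prec
        self.max_scale = max_scale
        n = basis.n
        self.nodes: dict[NodeIndex, FunctionNode] = {
            ROOT: FunctionNode(s=np.zeros((n, n, n)))
        }

    # -- structure -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.nodes)

    def is_leaf(self, idx: NodeIndex) -> bool:
        return self.nodes[idx].is_leaf

    def leaves(self):
        return (i for i, nd in self.nodes.items() if nd.is_leaf)

    def internal(self):
        return (i for i, nd in self.nodes.items() if not nd.is_leaf)

    def depth(self) -> int:
        return max(i[0] for i in self.nodes)

    def check_structure(self):
        """Raise if the octree is not complete (every non-leaf has 8 children)."""
        for idx, nd in self.nodes.items():
            if nd.is_leaf:
                continue
            for c in node_children(idx):
                if c not in self.nodes:
                    raise ValueError(f"incomplete octree: missing child {c} of {idx}")

    # -- scalar summaries ----------------------------------------------
    def norm_sq(self) -> float:
        tot = float(np.sum(self.nodes[ROOT].s ** 2))
        for idx in self.internal():
            tot += float(np.sum(self.nodes[idx].d ** 2))
        return tot

    def norm(self) -> float:
        return float(np.sqrt(self.norm_sq()))

    def integral(self) -> float:
        """Integral of the function over the domain (physical units)."""
        b = self.basis
        ivec = b.quad_w @ b.eval_scaling(b.quad_x)  # int phi_p over [0,1]
        s = self.nodes[ROOT].s
        return float(
            self.domain.edge ** 1.5
            * np.einsum("p,q,r,pqr->", ivec, ivec, ivec, s)
        )

    # -- coefficient access --------------------------------------------
    def scaling_on(self, idx: NodeIndex, memo: dict | None = None) -> np.ndarray:
        """Scaling coefficients on an arbitrary box at or below the leaf level.

        Boxes below a leaf are reached by exact polynomial refinement
        (backward two-scale transform with zero wavelet part).
        """
        nd = self.nodes.get(idx)
        if nd is not None:
            return nd.s
        if memo is not None and idx in memo:
            return memo[idx]
        if idx[0] <= 0:
            raise KeyError(f"box {idx} outside tree")
        par = node_parent(idx)
        sp = self.scaling_on(par, memo)
        n = self.basis.n
        C = np.zeros((2 * n, 2 * n, 2 * n))
        C[:n, :n, :n] = sp
        S = _apply3(self.basis.filter.T, C)
        s0, lx, ly, lz = idx
        bx, by, bz = lx % 2, ly % 2, lz % 2
        out = S[bx * n : bx * n + n, by * n : by * n + n, bz * n : bz * n + n]
        if memo is not None:
            memo[idx] = out
        return out

    def child_block(self, idx: NodeIndex) -> np.ndarray:
        """Stacked scaling coefficients of the 8 children as a ``(2n,2n,2n)`` block."""
        n = self.basis.n
        S = np.empty((2 * n, 2 * n, 2 * n))
        for c in node_children(idx):
            bx, by, bz = c[1] % 2, c[2] % 2, c[3] % 2
            S[bx * n : bx * n + n, by * n : by * n + n, bz * n : bz * n + n] = (
                self.scaling_on(c)
            )
        return S

    # -- evaluation -----------------------------------------------------
    def evaluate(self, point) -> float:
        """Value of the leaf-local polynomial expansion at ``point``."""
        point = np.asarray(point, dtype=float)
        if not self.domain.contains(point):
            raise ValueError(
                f"point {point.tolist()} outside domain "
                f"(center {self.domain.center.tolist()}, edge {self.domain.edge})"
            )
        u = np.clip(self.domain.to_unit(point), 0.0, np.nextafter(1.0, 0.0))
        idx = ROOT
        while not self.nodes[idx].is_leaf:
            s, lx, ly, lz = idx
            t = u * 2 ** (s + 1)
            bx = 1 if t[0] - 2 * lx >= 1.0 else 0
            by = 1 if t[1] - 2 * ly >= 1.0 else 0
            bz = 1 if t[2] - 2 * lz >= 1.0 else 0
            idx = (s + 1, 2 * lx + bx, 2 * ly + by, 2 * lz + bz)
        s, lx, ly, lz = idx
        t = u * 2**s - np.array([lx, ly, lz], dtype=float)
        t = np.clip(t, 0.0, 1.0)
        phi = [self.basis.eval_scaling(np.array([t[dim]]))[0] for dim in range(3)]
        fac = (2.0 ** (3 * s) / self.domain.edge**3) ** 0.5
        return float(
            fac * np.einsum("p,q,r,pqr->", phi[0], phi[1], phi[2], self.nodes[idx].s)
        )

    def __call__(self, point) -> float:
        return self.evaluate(point)

    # -- maintenance ----------------------------------------------------
    def compress(self):
        """Recompute all internal (scaling, wavelet) blocks from leaf scaling, bottom-up."""
        self.check_structure()
        n = self.basis.n
        for idx in sorted(self.internal(), key=lambda i: -i[0]):
            S = self.child_block(idx)
            C = _apply3(self.basis.filter, S)
            nd = self.nodes[idx]
            nd.s = C[:n, :n, :n].copy()
            d = C.copy()
            d[:n, :n, :n] = 0.0
            nd.d = d

    def reconstruct(self):
        """Recompute every non-root scaling block top-down from root + wavelets."""
        self.check_structure()
        n = self.basis.n
        for idx in sorted(self.internal(), key=lambda i: i[0]):
            nd = self.nodes[idx]
            C = nd.d.copy()
            C[:n, :n, :n] = nd.s
            S = _apply3(self.basis.filter.T, C)
            for c in node_children(idx):
                bx, by, bz = c[1] % 2, c[2] % 2, c[3] % 2
                self.nodes[c].s = S[
                    bx * n : bx * n + n, by * n : by * n + n, bz * n : bz * n + n
                ].copy()

    def copy(self) -> "FunctionTree":
        out = FunctionTree(self.basis, self.domain, self.prec, self.max_scale)
        out.nodes = {
            i: FunctionNode(s=nd.s.copy(), d=None if nd.d is None else nd.d.copy())
            for i, nd in self.nodes.items()
        }
        return out

    def scale(self, a: float) -> "FunctionTree":
        out = self.copy()
        for nd in out.nodes.values():
            nd.s *= a
            if nd.d is not None:
                nd.d *= a
        return out

    # -- serialization ---------------------------------------------------
    FORMAT_VERSION = 1

    def save(self, path: str):
        """Single-file archive: header, domain, node index table, coefficient blocks."""
        idxs = sorted(self.nodes)
        n = self.basis.n
        leaf = np.array([self.nodes[i].is_leaf for i in idxs], dtype=bool)
        scal = np.stack([self.nodes[i].s for i in idxs])
        internal = [i for i in idxs if not self.nodes[i].is_leaf]
        wav = (
            np.stack([self.nodes[i].d for i in internal])
            if internal
            else np.zeros((0, 2 * n, 2 * n, 2 * n))
        )
        np.savez(
            path,
            version=np.array([self.FORMAT_VERSION]),
            order=np.array([self.basis.order]),
            family=np.array([self.basis.family]),
            center=self.domain.center,
            edge=np.array([self.domain.edge]),
            prec=np.array([self.prec]),
            index=np.array(idxs, dtype=np.int64),
            leaf=leaf,
            scaling=scal,
            wavelet=wav,
        )

    @classmethod
    def load(cls, path: str) -> "FunctionTree":
        z = np.load(path, allow_pickle=False)
        if int(z["version"][0]) != cls.FORMAT_VERSION:
            raise ValueError(f"unsupported tree container version {z['version'][0]}")
        basis = build_basis(int(z["order"][0]), str(z["family"][0]))
        dom = Domain(z["center"], float(z["edge"][0]))
        t = cls(basis, dom, float(z["prec"][0]))
        t.nodes = {}
        wi = 0
        for row, isleaf, s in zip(z["index"], z["leaf"], z["scaling"]):
            idx = tuple(int(v) for v in row)
            if isleaf:
                t.nodes[idx] = FunctionNode(s=s.copy())
            else:
                t.nodes[idx] = FunctionNode(s=s.copy(), d=z["wavelet"][wi].copy())
                wi += 1
        t.check_structure()
        return t


# ----------------------------------------------------------------------
# projection
# ----------------------------------------------------------------------


def zero_tree(basis: MultiwaveletBasis, domain: Domain) -> FunctionTree:
    return FunctionTree(basis, domain)


def _children_scaling_quadrature(f, tree: FunctionTree, idx: NodeIndex) -> np.ndarray:
    """Scaling coefficients of the 8 children of ``idx`` by Gauss-Legendre quadrature."""
    b = tree.basis
    n, nq = b.n, len(b.quad_x)
    s, lx, ly, lz = idx
    h = 1.0 / 2 ** (s + 1)
    # per-dimension unit coordinates, shape (2, nq)
    ux = (2 * lx + np.arange(2)[:, None] + b.quad_x[None, :]) * h
    uy = (2 * ly + np.arange(2)[:, None] + b.quad_x[None, :]) * h
    uz = (2 * lz + np.arange(2)[:, None] + b.quad_x[None, :]) * h
    U = np.stack(
        np.meshgrid(
            ux.reshape(-1), uy.reshape(-1), uz.reshape(-1), indexing="ij"
        ),
        axis=-1,
    )  # (2nq, 2nq, 2nq, 3)
    pts = tree.domain.from_unit(U)
    vals = np.asarray(f(pts), dtype=float)
    if not np.all(np.isfinite(vals)):
        bad = np.argwhere(~np.isfinite(vals))[0]
        p = pts[tuple(bad)]
        raise ValueError(f"function not finite at quadrature point {p.tolist()}")
    vals = vals.reshape(2, nq, 2, nq, 2, nq).transpose(0, 2, 4, 1, 3, 5)
    Q = b.coeffs_from_values  # (n, nq)
    fac = (tree.domain.edge * h) ** 1.5
    return fac * np.einsum("pa,qb,rc,xyzabc->xyzpqr", Q, Q, Q, vals, optimize=True)


def _assemble_child_block(cs: np.ndarray, n: int) -> np.ndarray:
    """(2,2,2,n,n,n) child scaling -> stacked (2n,2n,2n) block."""
    return cs.transpose(0, 3, 1, 4, 2, 5).reshape(2 * n, 2 * n, 2 * n)


def project(
    f,
    domain: Domain,
    prec: float,
    basis: MultiwaveletBasis | int = 5,
    max_scale: int = DEFAULT_MAX_SCALE,
    min_scale: int = 2,
    norm_hint: float | None = None,
    threshold_rule=refinement_threshold,
) -> FunctionTree:
    """Project a pointwise-evaluable function onto an adaptive multiwavelet tree.

    The tree is refined while the wavelet norm of a box exceeds
    ``threshold_rule(prec, |f|)``; the function norm used by the rule is
    estimated during the build and the build is repeated once if the
    estimate was off by more than 50%.

    Parameters
    ----------
    f : callable
        Vectorized over point arrays of shape ``(..., 3)`` (bohr).
    domain : Domain
    prec : float
        Build precision; must be positive.
    basis : MultiwaveletBasis or int
        Basis object or polynomial order (Legendre family).
    """
    if prec <= 0:
        raise ValueError("prec must be positive")
    if isinstance(basis, int):
        basis = build_basis(basis)

    def build(fnorm_est: float) -> FunctionTree:
        tree = FunctionTree(basis, domain, prec, max_scale)
        tree.nodes = {}
        thr = threshold_rule(prec, fnorm_est)
        n = basis.n

        def visit(idx):
            cs = _children_scaling_quadrature(f, tree, idx)
            S = _assemble_child_block(cs, n)
            C = _apply3(basis.filter, S)
            d = C.copy()
            d[:n, :n, :n] = 0.0
            dn = float(np.sqrt(np.sum(d * d)))
            want = dn > thr or idx[0] < min_scale
            if want and idx[0] >= max_scale:
                raise RuntimeError(
                    f"refinement exceeded maximum scale {max_scale} at box {idx}"
                )
            if not want:
                tree.nodes[idx] = FunctionNode(s=C[:n, :n, :n].copy())
                return
            tree.nodes[idx] = FunctionNode(s=C[:n, :n, :n].copy(), d=d)
            for b, c in enumerate(node_children(idx)):
                bx, by, bz = b >> 2 & 1, b >> 1 & 1, b & 1
                tree.nodes[c] = FunctionNode(s=cs[bx, by, bz].copy())
                visit(c)

        visit(ROOT)
        tree.compress()
        _collapse_converged(tree, thr)
        return tree

    est = norm_hint
    if est is None:
        probe = FunctionTree(basis, domain, prec, max_scale)
        cs = _children_scaling_quadrature(f, probe, ROOT)
        est = float(np.sqrt(np.sum(cs * cs)))
    tree = build(est)
    actual = tree.norm()
    if actual > 0 and not (0.5 < actual / max(est, 1e-300) < 2.0):
        tree = build(actual)
    return tree


def _collapse_converged(tree: FunctionTree, thr: float):
    """Collapse forced-refinement subtrees whose detail is below threshold."""
    changed = True
    while changed:
        changed = False
        for idx in sorted(tree.internal(), key=lambda i: -i[0]):
            nd = tree.nodes[idx]
            kids = node_children(idx)
            if all(tree.nodes[c].is_leaf for c in kids) and nd.wavelet_norm() <= thr:
                for c in kids:
                    del tree.nodes[c]
                nd.d = None
                changed = True


# ----------------------------------------------------------------------
# transforms and truncation
# ----------------------------------------------------------------------


def mw_transform(tree: FunctionTree, direction: str) -> FunctionTree:
    """Forward ("compress") or backward ("reconstruct") two-scale transform.

    The returned tree has the same structure; compression refreshes the
    wavelet blocks from the leaf scaling coefficients, reconstruction
    refreshes all scaling blocks from root + wavelets.  The round trip
    is the identity.
    """
    if direction not in ("compress", "reconstruct"):
        raise ValueError("direction must be 'compress' or 'reconstruct'")
    out = tree.copy()
    if direction == "compress":
        out.compress()
    else:
        out.reconstruct()
    return out


def truncate(tree: FunctionTree, prec: float) -> FunctionTree:
    """Remove subtrees while the total discarded wavelet norm stays within budget.

    Collapses leaf-fringe boxes in order of increasing wavelet norm
    until the accumulated discarded norm would exceed ``prec * |f|``,
    which guarantees ``|before - after| <= prec * |before|``.
    """
    if prec <= 0:
        raise ValueError("prec must be positive")
    out = tree.copy()
    budget = (prec * out.norm()) ** 2

    def collapsible(idx):
        nd = out.nodes[idx]
        return not nd.is_leaf and all(
            out.nodes[c].is_leaf for c in node_children(idx)
        )

    heap = []
    for idx in out.internal():
        if collapsible(idx):
            w = out.nodes[idx].wavelet_norm()
            heapq.heappush(heap, (w * w, idx))
    spent = 0.0
    while heap:
        w2, idx = heapq.heappop(heap)
        if idx not in out.nodes or not collapsible(idx):
            continue
        if not np.isclose(w2, out.nodes[idx].wavelet_norm() ** 2):
            heapq.heappush(heap, (out.nodes[idx].wavelet_norm() ** 2, idx))
            continue
        if spent + w2 > budget:
            break
        for c in node_children(idx):
            del out.nodes[c]
        out.nodes[idx].d = None
        spent += w2
        if idx != ROOT:
            par = node_parent(idx)
            if collapsible(par):
                heapq.heappush(heap, (out.nodes[par].wavelet_norm() ** 2, par))
    return out


def evaluate(tree: FunctionTree, point) -> float:
    """Module-level alias for :meth:`FunctionTree.evaluate`."""
    return tree.evaluate(point)
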
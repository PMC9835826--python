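"""Arithmetic on function trees and node-blocked orbital-set algebra.

Addition, pointwise multiplication and inner products operate on the
union grid of their operands; coefficients below a tree's own leaves
are obtained by exact polynomial refinement, so linearity is exact on
shared nodes.  Inner products exploit orthonormality of the multi-
wavelet basis: only nodes present in both trees contribute (the root
scaling product is included exactly alongside the wavelet products).

Matrix elements between two orbital sets are evaluated either as a
nested loop of pairwise inner products or node-blocked: per node, the
stacked coefficient rows of the contributing bra and ket orbitals are
multiplied as one dense matrix product, and nodes absent from either
side are skipped (the implicit screening the block census records).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .screening import ScreeningLedger
from .tree import (
    ROOT,
    FunctionNode,
    FunctionTree,
    _apply3,
    node_children,
    truncate,
)

__all__ = [
    "add",
    "multiply",
    "inner_product",
    "OrbitalSet",
    "LocalView",
    "matrix_elements_blocked",
    "matrix_elements_loop",
    "rotate",
    "to_local_view",
    "from_local_view",
]


def _check_compatible(a: FunctionTree, b: FunctionTree):
    if a.basis is not b.basis and (
        a.basis.order != b.basis.order or a.basis.family != b.basis.family
    ):
        raise ValueError("trees have different multiwavelet bases")
    if not a.domain.same_as(b.domain):
        raise ValueError("trees have different domains")


def _union_index_set(trees) -> set:
    idxs = set()
    for t in trees:
        idxs |= set(t.nodes)
    return idxs


def add(
    a: FunctionTree,
    b: FunctionTree,
    coeff_a: float = 1.0,
    coeff_b: float = 1.0,
    prec: float | None = None,
) -> FunctionTree:
    """Linear combination ``coeff_a * a + coeff_b * b`` on the union grid."""
    _check_compatible(a, b)
    idxs = _union_index_set([a, b])
    out = FunctionTree(a.basis, a.domain, prec or a.prec, a.max_scale)
    out.nodes = {}
    memo_a, memo_b = {}, {}
    for idx in idxs:
        leaf = all(c not in idxs for c in node_children(idx))
        sa = a.scaling_on(idx, memo_a)
        sb = b.scaling_on(idx, memo_b)
        nd = FunctionNode(s=coeff_a * sa + coeff_b * sb)
        if not leaf:
            nd.d = np.zeros_like(a.nodes[ROOT].s, shape=(1,))  # placeholder
        out.nodes[idx] = nd
    out.compress()
    if prec is not None:
        out = truncate(out, prec)
    return out


def _product_children(a, b, idx, memo_a, memo_b):
    """(scaling, wavelet, child-scaling) of the pointwise product on box ``idx``.

    Child scaling coefficients are obtained by sampling both factors at
    the quadrature points of the eight children, multiplying values, and
    projecting back; the two-scale transform then yields the box's own
    scaling and wavelet blocks.
    """
    basis = a.basis
    n = basis.n
    E = basis.values_from_coeffs  # (nq, n)
    Q = basis.coeffs_from_values  # (n, nq)
    s_child = idx[0] + 1
    fac = (2.0 ** (3 * s_child) / a.domain.edge**3) ** 0.5
    cs = np.empty((2, 2, 2, n, n, n))
    for bi, c in enumerate(node_children(idx)):
        sa = a.scaling_on(c, memo_a)
        sb = b.scaling_on(c, memo_b)
        W = fac * _apply3(E, sa) * _apply3(E, sb)  # physical values / fac
        cs[bi >> 2 & 1, bi >> 1 & 1, bi & 1] = _apply3(Q, W)
    S = cs.transpose(0, 3, 1, 4, 2, 5).reshape(2 * n, 2 * n, 2 * n)
    C = _apply3(basis.filter, S)
    d = C.copy()
    d[:n, :n, :n] = 0.0
    return C[:n, :n, :n].copy(), d, cs


def multiply(a: FunctionTree, b: FunctionTree, prec: float) -> FunctionTree:
    """Adaptive pointwise product with ``|result - a b| <= prec |a| |b|``.

    The result grid is the union grid refined once beyond the deeper
    factor, extended adaptively while the product's wavelet norm exceeds
    the threshold, then truncated.
    """
    _check_compatible(a, b)
    if prec <= 0:
        raise ValueError("prec must be positive")
    na, nb = a.norm(), b.norm()
    thr = prec * max(na * nb, 1e-300)
    idxs = _union_index_set([a, b])
    out = FunctionTree(a.basis, a.domain, prec, a.max_scale)
    out.nodes = {}
    memo_a, memo_b = {}, {}
    amp_fac = lambda s_: (2.0 ** (3 * s_) / a.domain.edge**3) ** 0.5

    def negligible(idx):
        # local product bound: sup-proxy of one factor times L2 of the other
        sa = a.scaling_on(idx, memo_a)
        sb = b.scaling_on(idx, memo_b)
        nsa = float(np.sqrt(np.sum(sa * sa)))
        nsb = float(np.sqrt(np.sum(sb * sb)))
        return amp_fac(idx[0]) * nsa * nsb <= 0.01 * thr

    def refine(idx):
        if negligible(idx):
            out.nodes[idx] = FunctionNode(s=np.zeros((a.basis.n,) * 3))
            return
        s, d, cs = _product_children(a, b, idx, memo_a, memo_b)
        dn = float(np.sqrt(np.sum(d * d)))
        if dn <= thr or idx[0] >= a.max_scale:
            out.nodes[idx] = FunctionNode(s=s)
            return
        out.nodes[idx] = FunctionNode(s=s, d=d)
        for c in node_children(idx):
            out.nodes[c] = FunctionNode(s=np.empty(0))
            refine(c)

    def visit(idx):
        if any(c in idxs for c in node_children(idx)):
            out.nodes[idx] = FunctionNode(s=np.empty(0), d=np.empty(0))
            for c in node_children(idx):
                visit(c)
        else:
            refine(idx)

    visit(ROOT)
    out.compress()
    nrm = out.norm()
    rel = 1.0 if nrm == 0.0 else min(thr / nrm, 1.0)
    return truncate(out, rel)


def inner_product(a: FunctionTree, b: FunctionTree) -> float:
    """Exact L2 inner product: root scaling product plus common-node wavelet products."""
    _check_compatible(a, b)
    tot = float(np.sum(a.nodes[ROOT].s * b.nodes[ROOT].s))
    smaller, larger = (a, b) if len(a.nodes) <= len(b.nodes) else (b, a)
    for idx, nd in smaller.nodes.items():
        if nd.d is None:
            continue
        other = larger.nodes.get(idx)
        if other is not None and other.d is not None:
            tot += float(np.sum(nd.d * other.d))
    return tot


# ----------------------------------------------------------------------
# orbital sets
# ----------------------------------------------------------------------


@dataclass
class OrbitalSet:
    """Ordered set of occupied-orbital trees with occupations and labels."""

    orbitals: list
    occupations: np.ndarray = None
    labels: list = None

    def __post_init__(self):
        if self.occupations is None:
            self.occupations = np.full(len(self.orbitals), 2.0)
        self.occupations = np.asarray(self.occupations, dtype=float)
        if self.labels is None:
            self.labels = [f"phi_{i}" for i in range(len(self.orbitals))]
        for t in self.orbitals[1:]:
            _check_compatible(self.orbitals[0], t)

    def __len__(self) -> int:
        return len(self.orbitals)

    def __iter__(self):
        return iter(self.orbitals)

    def __getitem__(self, i):
        return self.orbitals[i]

    @property
    def basis(self):
        return self.orbitals[0].basis

    @property
    def domain(self):
        return self.orbitals[0].domain

    def copy(self) -> "OrbitalSet":
        return OrbitalSet(
            [t.copy() for t in self.orbitals],
            self.occupations.copy(),
            list(self.labels),
        )

    def gram(self) -> np.ndarray:
        return matrix_elements_blocked(self, self)

    def norms(self) -> np.ndarray:
        return np.array([t.norm() for t in self.orbitals])


@dataclass
class LocalView:
    """Real-space (node-wise) view of an orbital set.

    Per node: the ids of orbitals refined on that node and their full
    coefficient blocks stacked one row per contributing orbital.
    """

    basis: object
    domain: object
    occupations: np.ndarray
    labels: list
    entries: dict = field(default_factory=dict)  # idx -> (ids tuple, (m,2n,2n,2n))


def to_local_view(oset: OrbitalSet) -> LocalView:
    """Switch from orbital-wise to node-wise storage; O(total nodes)."""
    n = oset.basis.n
    view = LocalView(
        basis=oset.basis,
        domain=oset.domain,
        occupations=oset.occupations.copy(),
        labels=list(oset.labels),
    )
    per_node: dict = {}
    for i, t in enumerate(oset.orbitals):
        for idx, nd in t.nodes.items():
            blk = np.zeros((2 * n, 2 * n, 2 * n))
            blk[:n, :n, :n] = nd.s
            if nd.d is not None:
                blk += nd.d
            per_node.setdefault(idx, []).append((i, blk))
    for idx, rows in per_node.items():
        ids = tuple(i for i, _ in rows)
        view.entries[idx] = (ids, np.stack([b for _, b in rows]))
    return view


def from_local_view(view: LocalView) -> OrbitalSet:
    """Inverse of :func:`to_local_view`; the round trip is coefficient-exact."""
    n = view.basis.n
    norb = len(view.labels)
    node_sets: list[dict] = [dict() for _ in range(norb)]
    for idx, (ids, blocks) in view.entries.items():
        for i, blk in zip(ids, blocks):
            node_sets[i][idx] = blk
    orbitals = []
    for i in range(norb):
        t = FunctionTree(view.basis, view.domain)
        t.nodes = {}
        for idx, blk in node_sets[i].items():
            s = blk[:n, :n, :n].copy()
            has_children = all(c in node_sets[i] for c in node_children(idx))
            if has_children:
                d = blk.copy()
                d[:n, :n, :n] = 0.0
                t.nodes[idx] = FunctionNode(s=s, d=d)
            else:
                t.nodes[idx] = FunctionNode(s=s)
        t.check_structure()
        orbitals.append(t)
    return OrbitalSet(orbitals, view.occupations.copy(), list(view.labels))


# ----------------------------------------------------------------------
# node-blocked matrix elements and rotations
# ----------------------------------------------------------------------


def matrix_elements_loop(bra: OrbitalSet, ket: OrbitalSet) -> np.ndarray:
    """Nested-loop oracle: pairwise inner products."""
    M = np.empty((len(bra), len(ket)))
    for i, ti in enumerate(bra):
        for j, tj in enumerate(ket):
            M[i, j] = inner_product(ti, tj)
    return M


def matrix_elements_blocked(
    bra: OrbitalSet,
    ket: OrbitalSet,
    ledger: ScreeningLedger | None = None,
    screen: bool = True,
) -> np.ndarray:
    """All ``<phi_i | tau_j>`` via per-node block matrix multiplications.

    For each multiwavelet node present on both sides, the stacked
    wavelet rows are multiplied as one dense matmul; the root scaling
    block is treated the same way.  With ``screen`` enabled (default)
    nodes absent from one side are skipped -- which changes nothing,
    since their coefficients are exactly zero -- and the skip counts are
    recorded in the ledger.
    """
    _check_compatible(bra.orbitals[0], ket.orbitals[0])
    same = bra is ket
    nb, nk = len(bra), len(ket)
    M = np.zeros((nb, nk))

    # root scaling contribution: every orbital contributes
    Sb = np.stack([t.nodes[ROOT].s.reshape(-1) for t in bra])
    Sk = Sb if same else np.stack([t.nodes[ROOT].s.reshape(-1) for t in ket])
    M += Sb @ Sk.T

    contrib_b: dict = {}
    for i, t in enumerate(bra.orbitals):
        for idx, nd in t.nodes.items():
            if nd.d is not None:
                contrib_b.setdefault(idx, []).append(i)
    if same:
        contrib_k = contrib_b
    else:
        contrib_k = {}
        for j, t in enumerate(ket.orbitals):
            for idx, nd in t.nodes.items():
                if nd.d is not None:
                    contrib_k.setdefault(idx, []).append(j)

    all_nodes = sorted(set(contrib_b) | set(contrib_k))
    for idx in all_nodes:
        ib = contrib_b.get(idx, [])
        jk = contrib_k.get(idx, [])
        if ledger is not None:
            ledger.count_block(True, weight=len(ib) * len(jk))
            ledger.count_block(False, weight=nb * nk - len(ib) * len(jk))
        if screen:
            if not ib or not jk:
                continue
            Db = np.stack([bra.orbitals[i].nodes[idx].d.reshape(-1) for i in ib])
            Dk = (
                Db
                if same and ib == jk
                else np.stack([ket.orbitals[j].nodes[idx].d.reshape(-1) for j in jk])
            )
            M[np.ix_(ib, jk)] += Db @ Dk.T
        else:
            zero = np.zeros(bra.basis.n**3 * 8)

            def row(t, k):
                nd = t.nodes.get(k)
                return (
                    zero
                    if nd is None or nd.d is None
                    else nd.d.reshape(-1)
                )

            Db = np.stack([row(t, idx) for t in bra.orbitals])
            Dk = Db if same else np.stack([row(t, idx) for t in ket.orbitals])
            M += Db @ Dk.T
    return M


def rotate(oset: OrbitalSet, A: np.ndarray, prec: float) -> OrbitalSet:
    """Node-wise linear combination ``phi~_i = sum_j A_ij phi_j``.

    Every node of the union grid is transformed independently -- both
    scaling and wavelet blocks, so no intermediate transforms are needed
    -- and each resulting orbital is truncated at ``prec``.
    """
    A = np.asarray(A, dtype=float)
    norb = len(oset)
    if A.shape != (norb, norb):
        raise ValueError(f"rotation matrix shape {A.shape} != ({norb}, {norb})")
    idxs = _union_index_set(oset.orbitals)
    internal = {i for i in idxs if any(c in idxs for c in node_children(i))}
    memos = [dict() for _ in range(norb)]
    n = oset.basis.n
    new_trees = [
        FunctionTree(oset.basis, oset.domain, prec, oset.orbitals[0].max_scale)
        for _ in range(norb)
    ]
    for t in new_trees:
        t.nodes = {}
    zero_d = np.zeros((2 * n, 2 * n, 2 * n))
    for idx in idxs:
        S = np.stack(
            [oset.orbitals[j].scaling_on(idx, memos[j]).reshape(-1) for j in range(norb)]
        )
        Snew = A @ S
        if idx in internal:
            D = np.stack(
                [
                    (
                        oset.orbitals[j].nodes[idx].d.reshape(-1)
                        if idx in oset.orbitals[j].nodes
                        and oset.orbitals[j].nodes[idx].d is not None
                        else zero_d.reshape(-1)
                    )
                    for j in range(norb)
                ]
            )
            Dnew = A @ D
        for i in range(norb):
            nd = FunctionNode(s=Snew[i].reshape(n, n, n))
            if idx in internal:
                nd.d = Dnew[i].reshape(2 * n, 2 * n, 2 * n)
            new_trees[i].nodes[idx] = nd
    out = [truncate(t, prec) for t in new_trees]
    return OrbitalSet(out, oset.occupations.copy(), list(oset.labels))
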
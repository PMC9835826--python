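# mwhf — adaptive multiwavelet Hartree–Fock at desk scale

`mwhf` is a real-space electronic-structure library for atoms and very
small molecules.  Orbitals, densities, and potentials are represented on
adaptive octrees of multiwavelet coefficient blocks with rigorous,
per-operation error control: a single precision parameter ε governs
every projection, product, convolution, and truncation.  The package is
aimed at people who want to study *how* multiresolution Hartree–Fock
works — the tree algebra, the separated-kernel convolutions, the
screening bookkeeping — on problems that fit on a laptop.

## The method in brief

A function is expanded on dyadic boxes (scale *s*, translation *l*)
in a tensor-product basis of orthonormal Legendre polynomials up to
degree *k* per direction; refined boxes additionally carry the wavelet
(detail) coefficients, so a node holds `(2(k+1))³` numbers in total.
The octree is deepened only while a box's wavelet norm exceeds
`ε·max(‖f‖, 1)`.

Instead of diagonalizing a discretized Fock operator, the occupied
orbitals are iterated through the bound-state Helmholtz Green's
function of the shifted kinetic-energy operator,

    φᵢ ← −2 G_μᵢ ∗ (V φᵢ − Σ_{j≠i} F_ij φⱼ),      G_μ(r) = e^{−μr}/(4πr),
    μᵢ = √(−2 F_ii),

a preconditioned fixed-point iteration that never applies a Laplacian.
The Poisson (`1/r`) and Helmholtz kernels are expanded as certified
sums of Gaussians, each of which factorizes over Cartesian directions,
so operator application reduces to banded block-Toeplitz matrix
products scale by scale.  Exact exchange `K φᵢ = Σⱼ φⱼ P[φⱼφᵢ]` screens
orbital pairs by their product norm and applies each Poisson
convolution under node-local thresholds derived from the pair partners;
a `ScreeningLedger` counts every `{i, j, n}` block and exchange pair
considered, computed, or neglected.

## Worked example

Hartree–Fock for a helium atom, straight from Python:

```python
import numpy as np
from mwhf import Molecule, ScfConfig, scf_solve

mol = Molecule.from_symbols(["He"], [np.zeros(3)])
state = scf_solve(mol, ScfConfig(precision=1e-4))
print(f"E(HF) = {state.total_energy:.6f} hartree")
print(f"orbital energy = {state.energies[0]:.4f} hartree")
print(f"iterations = {len(state.history)}")
```

prints

```
E(HF) = -2.860864 hartree
orbital energy = -0.9176 hartree
iterations = 8
```

The total energy sits within about 1 mH of the Hartree–Fock limit
(−2.861680 Ha) at ε = 10⁻⁴; the orbital energy is the familiar −0.918
Ha.  The same run from the shell, with a report, Fock matrix, and
screening-ledger dump:

```bash
mwhf scf he.xyz --prec MW4 --report he.json --ledger-tsv he_ledger.tsv
```

`MW4` is an alias for ε = 10⁻⁴; `mwhf project`, `mwhf convolve`, and
`mwhf census` exercise the projection, Poisson, and screening layers
individually.

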
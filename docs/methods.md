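# Methods

This note records the model, the numerical choices, and the limits of
validity of `mwhf`.  Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is quoted from
elsewhere.

## Multiwavelet representation

A scalar function on a cubic domain (edge `L`, bohr) is represented on
a complete octree of dyadic boxes.  Box `(s, l)` carries `(k+1)³`
scaling coefficients on a tensor-product basis of normalized shifted
Legendre polynomials, orthonormal under the physical L2 inner product;
non-leaf boxes also carry the `7(k+1)³` wavelet coefficients holding
the detail lost on coarsening, so the per-node total is `(2(k+1))³`
(4096 at order 7).  The wavelet rows of the two-scale filter are a
deterministic Householder completion of the orthogonal complement of
the scaling rows: any such completion spans the same detail space and
keeps all invariants (orthogonality, Parseval, vanishing wavelet
coefficients on polynomial input); fixing it once makes coefficient
layouts reproducible bit for bit.  Coefficients are ordered with the
polynomial index fastest in z, then y, then x.

Two families are implemented.  `legendre` (default) makes polynomial
reproduction exact, which many tests rely on; `interpolating`
(Lagrange cardinal functions at Gauss–Legendre points) is provided for
completeness.

### Refinement rule

Projection computes a box's eight children by `2(k+1)`-point
Gauss–Legendre quadrature per direction, filters to the parent, and
refines while the parent's wavelet norm exceeds

    thr = ε · max(‖f‖, 1).

The rule is deliberately scale-independent (the simplest testable
reading of threshold-controlled adaptivity); the norm is estimated
during the build and the build repeats once if the estimate was off by
more than 50%.  A forced minimum depth of 2 prevents narrow features
from being missed by root-level quadrature; converged forced boxes are
collapsed afterwards.  Refinement past scale 20 (or a user cap) raises
an error naming the cap.  Truncation collapses leaf-fringe boxes in
order of increasing wavelet norm until the accumulated discarded norm
would exceed `ε‖f‖`, which guarantees `‖before − after‖ ≤ ε‖before‖`.

Defaults: order `k = 5` (k = 7 available), domain edge = molecular
extent + 16 bohr (8 bohr padding per side), all lengths in bohr.

## Tree algebra

Addition and rotation act node-wise on the union grid; coefficients
below a tree's own leaves come from exact polynomial refinement, so
linearity is exact on shared nodes and no intermediate transforms are
needed (both scaling and wavelet blocks rotate).  Multiplication
samples both factors at the children of each union leaf, multiplies
point values, projects back, and keeps refining while the product's
wavelet norm exceeds `ε‖a‖‖b‖`; subtrees where a cheap local bound
(sup-proxy of one factor times the local norm of the other) puts the
product below 1% of that threshold are skipped outright — this is what
makes products of spatially separated orbitals nearly free.

Inner products use orthonormality: the root scaling product plus
wavelet products over nodes present in both trees.  The root scaling
contribution is included exactly (it is negligible for cost but not
for correctness).  Matrix elements between orbital sets are evaluated
per node as one dense matrix product of the stacked contributor rows;
nodes absent from either side are skipped, which changes nothing
(their coefficients are exactly zero) and is what the block census
counts.  A `LocalView` stores the same data keyed by node rather than
by orbital; the round trip is coefficient-exact.

## Separated kernels and convolution

`1/r` and `e^{−μr}/(4πr)` are expanded as sums of Gaussians by
trapezoid discretization of their integral representations; the step
is refined until a requested relative error is certified on a dense
log grid over `[r_min, r_max]`, and non-contributing terms are
trimmed.  Typical counts: 50–100 terms for 10⁻⁴–10⁻⁵ over four decades.
For μ > 0 the certified range is cut at the radius where the kernel
itself has decayed below the application precision.

A Gaussian term's action on scaling coefficients at one scale is three
banded block-Toeplitz products.  The 1D matrices are *exact* for any
exponent: Gaussian moments against the precomputed scaling-function
cross-correlation polynomials, evaluated by fixed quadrature for broad
terms and by the (contracting) erf recursion for sharp ones.

Each term is applied on the input tree's own leaf partition, clipped
one to two scales below the term's natural scale (the scale whose box
size matches the Gaussian width).  Finer detail is invisible to the
term — a smooth kernel against detail with `k+1` vanishing moments —
while at scales coarser than natural the term is essentially local and
the band is one or two boxes.  Because the partition is a faithful
representation of the input, its box seams carry only ε-sized jumps,
so representing each scale group's output at the group's own scale is
accurate; the output grid is input-driven (this is the main
approximation: output features far from any input refinement finer
than the local input grid are not resolved, which shows up as a
worst-point error of a few ε in closed-form checks while the origin
value of the Poisson test is well below ε).  Output boxes below 2% of
the (optionally screened) local threshold are pruned; surviving
contributions are assembled on their union grid and truncated at ε.

### Reference screening

Following the error-budget reading — local error × local reference
amplitude ≤ global precision — the effective precision at a box is
`ε / max(amp, ε)` with `amp` the largest pointwise reference amplitude
sampled at the box center and corners (a node-mean proxy would
underestimate the near edge of a decaying reference by orders of
magnitude).  Far from every reference the requirement relaxes to 1 and
whole output regions are pruned; where a reference is large the
requirement can be tighter than ε, which is the intended behavior of
"precision inversely proportional to the reference value" and is the
reading implemented here.

## Hartree–Fock

Restricted closed-shell only; one-electron systems are admitted as the
single exception (their Coulomb and exchange cancel exactly and are
skipped).  The SCF machinery:

* **Nuclear potential**: smoothed point charge `−Z u(r/c)/c` with an
  erf core plus two Gaussian corrections whose error integrates to
  high order against s-type densities.  The smoothing length
  `c = min(0.1, (17.6 ε)^{1/4.6})/Z` keeps the per-atom energy error
  near ε/100 (calibrated against the hydrogen density; at ε = 10⁻⁴,
  c = 0.1/Z gives ≈ 4·10⁻⁷ Ha for Z = 1).
* **Guess**: atom-centered s-type Gaussians with hydrogenic exponents
  (`8Z²/9π` for the 1s; two diffuse shells added for Z > 2), combined
  through the analytic one-electron problem in that tiny basis, then
  projected and Löwdin-orthonormalized.  Heavier atoms would need p
  shells; the supported SCF scope is H/He-row systems and small
  H-containing molecules.
* **Coulomb/exchange**: `J = P[ρ]` by Poisson convolution of the total
  density; `K φᵢ = Σⱼ φⱼ P[φⱼφᵢ]` with (a) pairs skipped when
  `‖φᵢφⱼ‖ ≤ ε/√n_pairs` (each skip is counted in the ledger, and the
  summed skip error stays below ε), (b) each Poisson application
  screened by references {φᵢ, φⱼ} so one potential serves both
  `K φᵢ` and `K φⱼ` (a shared cache reuses it), (c) per-term precision
  tightened by `1/√N_occ` with unit constant.
* **Update**: the Helmholtz step above, with `μ = √(−2ε_i)` floored at
  `ε_i ≥ −0.05` (early iterations can produce non-negative orbital
  energies).  The kinetic matrix comes free of derivatives from the
  identity `(T − ε_j) φ̃_j = −g_j` of the update itself; the first
  iteration uses the analytic Gaussian kinetic integrals of the guess,
  and a heat-semigroup route (`(S − ⟨i|e^{tΔ}|j⟩)/2t`, one Richardson
  step) exists for arbitrary sets at diagnostic accuracy (~10⁻³
  relative).  Orthonormalization is Löwdin `S^{−1/2}` via the
  node-wise rotation.
* **Energy**: standard restricted expression
  `E = Σᵢ occᵢ (T + V_nuc)ᵢᵢ + ½ Σᵢ occᵢ Jᵢᵢ − ½ Σᵢ occᵢ Kᵢᵢ + E_nn`.
* **Convergence**: max orbital residual below `10ε` and energy change
  below `10·(10ε)²`.  Internal operations (products, convolutions,
  rotations) run at `0.2ε` so the fixed-point noise floor sits safely
  below the convergence threshold.  Plain fixed-point iteration; no
  mixing is needed for the systems in scope.
* **Precision ladder**: a run can traverse strictly decreasing rungs,
  reusing the previous rung's orbitals directly — a multiwavelet
  function built at one precision is a valid (coarser) representation
  at any other.
* **Localization**: Foster–Boys by Jacobi 2×2 sweeps maximizing
  `Σᵢ ⟨i|r|i⟩²` with exact per-leaf dipole matrix elements; a rotation
  is accepted only if it improves the objective, so monotonicity holds
  by construction.  Off during SCF by default (atoms and tiny
  molecules gain nothing).

The in-process work queue of the assembly loops dispenses node blocks
and exchange pairs in deterministic lexicographic order, so runs with
identical inputs reproduce identical ledgers and energies.

## Screening accounting

A block is one `{i, j, n}` triple; the census multiplies the union
node count by the squared orbital count, and the ledger's conservation
identities (`total = computed + skipped`, pair total `n(n−1)/2`) are
asserted after every assembly.  Reports display blocks in the
million-rounded style alongside the raw integers.  Timers are
wall-clock diagnostics only and are never asserted on.

## Synthetic chains

The scaling studies use chains of unit-exponent, unit-norm Gaussians
spaced 3 bohr apart — an idealization of localized occupied orbitals
along a saturated chain.  Orbital products decay as `e^{−d²/2}` with
site distance `d`, so nearest-neighbor pairs survive the pair
threshold and everything beyond is neglected: computed pairs per
orbital saturate near 1 while the neglected fraction grows with chain
length.  What this shows is the *mechanism* of emergent linear scaling
under localization; real occupied orbitals have richer shapes, tails,
and near-degeneracies, so passing these tests says nothing
quantitative about real molecules beyond the mechanism itself.

## Problem sizes and tolerances used in the checks

The closed-form Poisson check runs at ε = 10⁻⁵ on a 16-bohr box; the
hydrogen fixed point and both atomic SCF runs at ε = 10⁻⁴ (order 5);
chains at ε = 10⁻³ with sizes 4/8/16.  These sizes exercise every code
path — deep nuclear refinement, multi-scale convolution, screening —
while each individual check completes in seconds to a few minutes on
one core.

## Known limitations

* Real orbitals, restricted closed shell, s-type guesses: no open
  shells, no heavier-than-first-row molecules in practice, no
  properties or gradients.
* The convolution output grid is input-driven; pointwise accuracy far
  from input refinement is a few ε rather than ε.
* Single cubic domain, free boundary conditions; very diffuse anions
  would need larger padding than the default 8 bohr.
* The heat-semigroup kinetic route is diagnostic-grade; production
  kinetic numbers come from the update identity (or the analytic
  guess).
* Parallelism is out of scope by design: the task queue preserves the
  granularity (node blocks, exchange pairs) but runs in-process.
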
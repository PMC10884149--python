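# Methods

## Model

A diploid chromosome is a string of beads: each of the `n` genomic loci
(fixed-size bins) has two beads, one per homolog, at unknown positions
`x_i, y_i ∈ R³`. Contact counts follow the power law `c = γ d^α` with
`γ = 1` and `α = −2` throughout; setting `γ = 1` means the reconstruction
is recovered up to global scale, which matches the similarity-invariant
RMSD used for evaluation.

Partially phased Hi-C data splits the loci into unambiguous (`U`, beads
distinguishable via SNPs) and ambiguous (`A`) sets, and yields three
matrices: `cU` (2n×2n, single bead-pair terms), `cP` (2n×n, two-term sums:
phased bead against an unphased locus), and `cA` (n×n, four-term sums).
Entries the partition semantics do not define (self contacts, pairs
outside the class) carry an explicit availability mask rather than
sentinel zeros, because an *observed* zero count is meaningful in the
distance-geometry objective (it contributes the λ-penalty term) while an
unavailable entry is not.

## The four reconstruction stages

**1. Unambiguous beads by distance geometry.** The 2|U| phased beads are
estimated from the weighted least-squares objective

    min_Z  Σ_{c≠0} √c (1/c − ‖z_i−z_j‖²)² + λ Σ_{c=0} ‖z_i−z_j‖²,  λ = 0.01.

The √c weights downweight low counts (higher relative noise); the λ term
pushes unobserved pairs apart. The objective is minimized through its
convex surrogate over the centered positive-semidefinite Gram matrix
(squared distances are affine in G): projected gradient descent with
eigenvalue-clamping projection onto the PSD cone, initialized from
classical MDS on the model distances `d² = 1/c`, followed by rank-3
spectral extraction `QΛ₃^{1/2}` and an L-BFGS polish of the coordinate
objective. Negative eigenvalues among the top three are clamped exactly to
zero (no relative cutoff — simple and monotone).

**2. Ambiguous pairs by polynomial systems.** For an ambiguous locus with
unknown beads (x, y), six unambiguous anchor beads t with counts
`c_t = ‖x−t‖⁻² + ‖y−t‖⁻²` give, after clearing denominators, six quartics

    ‖x−t‖² + ‖y−t‖² = c_t ‖x−t‖² ‖y−t‖²

in six unknowns, swap-symmetric under (x, y) ↦ (y, x). At generic complex
parameters the system has 80 finite nonsingular solutions (40 orbits),
bounded by the mixed volume 1280 of its Newton polytopes and the Bézout
number 4⁶ = 4096; all three numbers are recomputed by this package (see
Certificates).

The solver is a two-phase parameter homotopy. Phase 1 solves the system
once at random complex parameters by monodromy: a planted solution is
carried around random triangular loops in the 24-dimensional parameter
space, the swap symmetry doubling every discovery, until the deduplicated
count is stable for three consecutive loops (at least eight loops, at most
eighty). Phase 2 tracks one representative per swap orbit — 40 paths — to
the target parameters along a straight segment bent by a random complex
reparametrization (the "gamma trick"), so a real target is approached from
generic complex directions. The tracker is an adaptive-step
predictor–corrector in complex arithmetic: RK4 predictor on the Davidenko
equation `dz/dτ = −J⁻¹ ∂F/∂τ`, Newton corrector, step halving on corrector
failure (minimum step 1e−12), batched across paths with a shared adaptive
step; paths that keep failing while the rest advance are re-tracked
individually. Endpoints are Newton-polished and certified to relative
residual < 1e−8, and deduplicated at 1e−8.

Per locus, anchors are drawn from the pool of the 20 unambiguous *beads*
with the highest partially ambiguous count to that locus (both homolog
beads of an unambiguous locus are eligible). N = 5 six-anchor systems are
solved; solutions whose imaginary max-norm is below 0.15 are kept as real
candidates (the tolerance is absolute and assumes coordinates at unit step
scale — the CLI rescales real data so the median nonzero unambiguous
distance is O(1)). A draw with no approximately real solution is redrawn,
up to 100 draws in total. The per-locus estimate is the consensus: each
candidate set is augmented with its swap images and the product of the N
sets is searched exhaustively for the tuple minimizing the summed
deviation from the tuple mean; that mean is the estimate. If fewer than
two nonempty sets are found the locus falls back to the average of the
bead midpoints of its nearest unambiguous neighbors (one per side) and is
flagged, so downstream consumers can ignore or interpolate it.

**3. Joint refinement.** The per-locus estimates use six anchors at a
time; a quasi-Newton (L-BFGS) pass then refits all ambiguous pairs jointly
against every available `cP` entry,

    min Σ_{i∈U, j∈A} (cP_{i,j} − ‖x_i−x_j‖⁻² − ‖x_i−y_j‖⁻²)²
                   + (cP_{i+n,j} − ‖y_i−x_j‖⁻² − ‖y_i−y_j‖⁻²)²,

with the unambiguous coordinates fixed. Ambiguous–ambiguous `cA` terms are
deliberately not used. Defaults: gradient tolerance 1e−6, 500 iterations.
Steps probing a configuration with a contributing distance below ~1e−9 are
rejected by returning a large objective value to the line search; if the
first line search fails the initial point is returned with a warning flag.
The refined objective never exceeds the initial one.

**4. Swap disambiguation.** Every earlier stage is invariant under
swapping (x_i, y_i) per ambiguous locus. Assuming homologs occupy separate
territories, the final assignment minimizes the summed squared consecutive
jumps Σ ‖x_i−x_{i+1}‖² + ‖y_i−y_{i+1}‖² over the 2^|A| swap choices.
With signs s_i ∈ {±1} and link products
w_{i,i+1} = (x_i−y_i)·(x_{i+1}−y_{i+1}) this is equivalent to maximizing
Σ w_{i,i+1} s_i s_{i+1}, which decouples over contiguous chunks of
ambiguous loci delimited by unambiguous ones and is solved exactly by sign
recursion: chunks with a free end propagate `s_{i+1} = sgn(w) s_i` from
the fixed end; an interior chunk may be forced to violate one link, and
the optimal violated link is the one with smallest |w|. Conventions:
`sgn(0) := +1`; ties for the weakest link break to the smallest index;
if no locus is unambiguous at all (outside the method's setting) `s_1` is
fixed to +1 and the forward recursion runs — a documented extension. The
recursion is property-tested against exhaustive 2^|A| enumeration.

## Certificates

Three computations certify that the problem is well posed:

* **Six-anchor finiteness.** The 6×6 matrix with rows
  `[‖x*−t‖^{α−2}(x*−t), ‖y*−t‖^{α−2}(y*−t)]` at the unit-cube
  configuration (x* = origin, y* = opposite vertex, the six remaining
  vertices as anchors) has determinant −675/1024 ≠ 0 at α = −2, computed
  exactly with sympy.
* **Fully ambiguous identifiability.** The 66×72 Jacobian of the map
  sending 12 bead pairs to their 66 four-term inverse-square sums has full
  rank 66 at random rational configurations. Rows are cleared to integers
  by an exact rational scaling; full rank is certified by modular
  elimination (rank over Z/p lower-bounds rank over Q, so full modular rank
  is a proof), with fraction-arithmetic Gaussian elimination as the exact
  fallback for deficient cases. At α = +2 the same computation yields rank
  42 at the sampled random configurations — the reconstruction problem is
  not finitely identifiable there.
* **Root counts.** The monodromy phase-1 count (80, forming 40 swap
  orbits, stable across seeds) is bounded by the mixed volume of the six
  Newton polytopes — 1280, computed from the symbolically expanded
  supports by inclusion–exclusion over Minkowski-sum hull volumes — which
  is bounded by the Bézout number 4096.

## Synthetic data

The generator emulates the benchmark conditions used throughout: two
homolog chains as fixed-step random walks (steps uniform on the sphere,
implemented as normalized Gaussians) or as parallel circular helices
(radius 1, pitch 0.3 per turn, equal arc-length spacing — the helix
parameters are this package's choice), 60 loci by default, half of them
ambiguous at uniformly random positions, counts from the forward model,
and multiplicative noise `c ← c(1+δ)`, `δ ~ Uniform(−ε, ε)`, drawn once
per unordered pair so symmetric matrices stay symmetric, independently for
the three matrices even though their noiseless values are algebraically
linked. Homolog 2 is translated by five step lengths by default so the
territory-separation assumption of stage 4 holds in fixtures; the
separation is configurable because it is a modelling assumption, not a
measured constant.

What the generator does *not* emulate: sequencing-depth integer counts and
their Poisson noise, unmappable or low-coverage bins, loci participating
simultaneously in all three count classes (real partially phased data;
handled separately by `filter_loci`), and polymer physics beyond the
random-walk geometry. Passing tests therefore demonstrate correctness of
the algorithms under the power-law model with uniform multiplicative
noise, not performance on arbitrary real Hi-C libraries.

## Real-data preparation

`filter_loci` prepares real partially phased matrices (where every locus
can have counts of all three classes) for the pure-partition setting: loci
are sorted by total contact count and the lowest `drop_lowest` (default
47) removed; a locus is ambiguous iff less than 40% of its total count
comes from contacts where its beads were distinguished. A locus's phased
total counts its `cU` and `cP` rows; its unphased total counts its `cP`
columns and `cA` rows. Counts are then redistributed so every pair is
wholly one class: counts phased for a now-ambiguous locus are summed into
its ambiguous bins; counts unphased for a now-unambiguous locus are split
over its two beads proportionally to the observed phased profile (evenly
when no profile exists). The redistribution conserves pair totals and is
this package's documented choice, switchable off; the drop count is a
parameter, with the consecutive-total-ratio peak available as a diagnostic
for choosing it.

## Numerical choices and problem sizes

* Tracker: corrector tolerance 1e−8 on the relative residual
  (scale 1 + |qx| + |qy| + |c·qx·qy| per equation), divergence cutoff
  ‖z‖ > 1e8, endpoint polish to 1e−8, dedup at 1e−8 relative.
* The Gram-stage projected gradient runs at most 200 iterations with
  Armijo backtracking; the coordinate polish runs L-BFGS to `ftol` 1e−14.
* Procrustes alignment allows reflections (O(3)) and optimizes scale; the
  RMSD is evaluated from the explicit residual to avoid cancellation. The
  printed evaluation does not minimize over the global homolog relabeling
  (x, y) ↔ (y, x); an option exposes it.
* The bipartite index excludes self pairs i = j from the intra-superdomain
  sums (the raw 1/d² kernel diverges there) and normalizes intra blocks by
  ordered-pair counts h(h−1) and (n−h)(n−h−1); the inter term keeps the
  2/(h(n−h)) normalization.
* Test problem sizes: end-to-end noiseless recovery at n = 60 with 50%
  ambiguous loci; the noise sweep (ε = 0.05 vs 0.3, 20 seeds, mean RMSD
  nondecreasing) at n = 12 with 50% ambiguous loci — the smallest size at
  which the method's |U| ≥ 6 precondition holds at that fraction — and a
  per-locus anchor-redraw budget of 30 instead of the default 100, both
  chosen to keep the property check cheap while preserving the monotone
  degradation being tested (a tighter redraw budget only produces more
  fallback loci at high noise, i.e. it cannot flatten the trend);
  exhaustive swap-enumeration oracles at n ≤ 12.

## Known limitations

* α is fixed at −2; no estimation of the conversion factor from data.
* The method needs at least six unambiguous loci; with fewer the
  polynomial stage is undefined (and the distance-geometry stage needs at
  least four).
* The imaginary-part tolerance 0.15 is scale-dependent; data far from unit
  step scale must be rescaled (the CLI path does this automatically).
* At high noise the per-locus systems may lack approximately real
  solutions; such loci fall back to neighbor averages and are flagged.
  Their positions are interpolations, not measurements.
* The seven-anchor over-determined system is not used: under noise it
  typically has no solutions at all, and whether it pins the pair uniquely
  in the noiseless case is open.
* Monodromy stopping is heuristic (stable count over consecutive loops);
  the 80-count is cross-checked against the mixed-volume bound but not
  certified by interval arithmetic.
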
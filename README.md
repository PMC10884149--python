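# snlc

Consensus 3D genome reconstruction for diploid organisms from **partially
phased Hi-C data**.

## The problem

Hi-C experiments measure pairwise contact counts between genomic loci. In a
diploid genome every locus exists twice — once per homolog — and a contact
read can only be attributed to a specific homolog when it overlaps a
distinguishing SNP. Real datasets are therefore *partially phased*: some
loci are unambiguous (their two beads `x_i, y_i ∈ R³` are distinguishable),
the rest are ambiguous. Under the power-law model `c = d^α` with `α = −2`,
the data are three matrices

* `cU` — unambiguous counts, one term `‖z_i − z_j‖⁻²` per bead pair,
* `cP` — partially ambiguous counts, two-term sums,
* `cA` — ambiguous counts, four-term sums,

and the task is to recover all `2n` bead positions up to a rigid motion and
global scale. This package is for computational biologists who want
haplotype-resolved 3D structures from such data, and for people studying
when that reconstruction problem is solvable at all.

## The method

Four stages (the package name abbreviates them):

1. **S**emidefinite-style distance geometry — the unambiguous beads
   minimize `Σ √c (1/c − d²)² + 0.01·Σ_{c=0} d²` via a convex Gram-matrix
   relaxation, rank-3 spectral extraction, and a quasi-Newton polish.
2. **N**umerical algebraic geometry — each ambiguous pair (x, y) solves six
   quartics `‖x−t‖² + ‖y−t‖² = c_t‖x−t‖²‖y−t‖²` for six anchor beads t.
   The system has 80 complex solutions generically; a two-phase homotopy
   (monodromy start, then 40 parameter-homotopy paths, one per swap orbit)
   finds them, and a consensus over N = 5 anchor draws picks the
   approximately real solution consistent across draws.
3. **L**ocal optimization — all ambiguous pairs are refit jointly against
   every partially ambiguous count by L-BFGS, unambiguous beads fixed.
4. **C**lustering — the per-locus swap ambiguity (x_i, y_i) ↔ (y_i, x_i) is
   broken exactly: minimizing consecutive intra-homolog jumps reduces to
   maximizing `Σ w_{i,i+1} s_i s_{i+1}`, `s_i ∈ {±1}`, solved in closed
   form per chunk of ambiguous loci.

The package also ships the identifiability certificates that justify the
method (a unit-cube determinant for six-anchor finiteness, an exact 66×72
Jacobian rank for the fully ambiguous setting, mixed-volume/Bézout root
bounds), the synthetic benchmark generator, Procrustes RMSD evaluation, the
bipartite index for inactive-X superdomain structure, and filtering for
real partially phased matrices. See `docs/methods.md` for details.

## Worked example

```python
import numpy as np
from snlc import (SimulationConfig, make_dataset, reconstruct,
                  ReconstructionConfig, procrustes_rmsd)

truth, partition, contacts = make_dataset(
    SimulationConfig(n=20, ambiguous_fraction=0.5, epsilon=0.0, seed=3))
result = reconstruct(contacts, partition, ReconstructionConfig(seed=1))
align = procrustes_rmsd(result.structure, truth)
print(f"RMSD: {align.rmsd:.2e}")
print(f"flags: {sorted(set(result.flags.values()))}")
print(f"sign vector minimum attained: {result.diagnostics['sign_objective']:.4f}")
```

prints

```
RMSD: 1.10e-06
flags: ['refined']
sign vector minimum attained: 38.0000
```

A 20-locus chromosome pair with half its loci ambiguous is simulated at
step length 1, noiseless counts are computed, and the four stages recover
the structure to an RMSD of ~1e−6 step lengths after optimal similarity
alignment — i.e. exactly, up to solver tolerances. Every ambiguous locus
was estimated by the polynomial solver and refined (`refined`); loci where
the solver had to fall back to neighbor averaging would be flagged
`fallback`. The last line is the attained minimum of the swap-disambiguation
objective — the summed squared consecutive jumps along both chains, which
for a correct assignment of a unit-step pair equals 2(n−1) = 38 exactly,
confirming no homolog labels were flipped. With
noise (`epsilon=0.3`) the RMSD degrades gracefully to the order of one step
length.

The same pipeline is scriptable from the shell:

```sh
snlc simulate --n 60 --ambiguous-fraction 0.5 --epsilon 0.1 --seed 7 --out data/
snlc reconstruct --data data/ --seed 1 --out estimate.tsv
snlc evaluate --estimate estimate.tsv --truth data/truth.tsv
snlc verify                 # run all identifiability certificates
```

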
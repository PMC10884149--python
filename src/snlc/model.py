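"""Core data types and the forward contact model.

A diploid chromosome is modelled as a string of beads: each of the ``n``
genomic loci has two beads, one per homolog, with coordinates ``x_i`` and
``y_i`` in R^3.  Contact counts follow the power law ``c = gamma * d**alpha``
with ``gamma = 1`` and (throughout this package) ``alpha = -2``.

Partially phased Hi-C data yields three count matrices:

* ``cU`` (2n x 2n) — unambiguous counts between beads of phased loci; bead
  ``i`` is ``x_i`` and bead ``n+i`` is ``y_i``.
* ``cP`` (2n x n) — partially ambiguous counts between a phased bead and an
  unphased locus; each entry is a sum of two bead-level counts.
* ``cA`` (n x n) — ambiguous counts between two unphased loci; each entry is
  a sum of four bead-level counts.

Entries that the phasing semantics do not define (self contacts, pairs
outside the U/A partition) are kept at 0 and flagged unavailable in an
explicit boolean mask: an *observed* zero count is meaningful (it enters the
penalty term of the distance-geometry objective), an unavailable entry is
not.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

__all__ = [
    "Structure3D",
    "LociPartition",
    "ContactData",
    "contacts_from_structure",
    "add_noise",
]


@dataclass
class Structure3D:
    """Positions of the 2n beads of a homolog pair.

    ``x`` holds homolog 1, ``y`` homolog 2; row ``i`` of each is locus ``i``
    (0-based internally, 1-based in file formats and documentation).
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 2 or self.x.shape[1] != 3:
            raise ValueError("x must be an (n, 3) array")
        if self.y.shape != self.x.shape:
            raise ValueError("x and y must have the same shape")
        if self.x.shape[0] < 1:
            raise ValueError("need at least one locus")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("coordinates must be finite")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def z(self) -> np.ndarray:
        """All 2n bead coordinates stacked: rows 0..n-1 are x, n..2n-1 are y."""
        return np.vstack([self.x, self.y])

    @classmethod
    def from_z(cls, z: np.ndarray) -> "Structure3D":
        z = np.asarray(z, dtype=float)
        if z.ndim != 2 or z.shape[1] != 3 or z.shape[0] % 2:
            raise ValueError("z must be a (2n, 3) array")
        n = z.shape[0] // 2
        return cls(z[:n].copy(), z[n:].copy())

    def copy(self) -> "Structure3D":
        return Structure3D(self.x.copy(), self.y.copy())


@dataclass
class LociPartition:
    """Disjoint split of the loci into unambiguous (U) and ambiguous (A) sets."""

    n: int
    U: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        self.U = np.asarray(sorted(int(i) for i in np.atleast_1d(self.U)), dtype=int)
        self.A = np.asarray(sorted(int(i) for i in np.atleast_1d(self.A)), dtype=int)
        if self.n < 1:
            raise ValueError("n must be positive")
        all_idx = np.concatenate([self.U, self.A])
        if len(set(all_idx.tolist())) != len(all_idx):
            raise ValueError("U and A must be disjoint")
        if sorted(all_idx.tolist()) != list(range(self.n)):
            raise ValueError("U and A must partition {0, ..., n-1}")

    @classmethod
    def all_unambiguous(cls, n: int) -> "LociPartition":
        return cls(n, np.arange(n), np.array([], dtype=int))

    def is_ambiguous(self, i: int) -> bool:
        return i in set(self.A.tolist())


@dataclass
class ContactData:
    """The three contact count matrices plus the power-law parameters.

    ``mU``, ``mP`` and ``mA`` are availability masks; unavailable entries are
    stored as 0 but must not be interpreted as observed zero counts.
    """

    n: int
    cU: np.ndarray
    cP: np.ndarray
    cA: np.ndarray
    mU: np.ndarray
    mP: np.ndarray
    mA: np.ndarray
    alpha: Fraction = Fraction(-2)
    gamma: float = 1.0

    def __post_init__(self) -> None:
        n = self.n
        self.cU = np.asarray(self.cU, dtype=float)
        self.cP = np.asarray(self.cP, dtype=float)
        self.cA = np.asarray(self.cA, dtype=float)
        self.mU = np.asarray(self.mU, dtype=bool)
        self.mP = np.asarray(self.mP, dtype=bool)
        self.mA = np.asarray(self.mA, dtype=bool)
        if self.cU.shape != (2 * n, 2 * n) or self.mU.shape != (2 * n, 2 * n):
            raise ValueError("cU/mU must be (2n, 2n)")
        if self.cP.shape != (2 * n, n) or self.mP.shape != (2 * n, n):
            raise ValueError("cP/mP must be (2n, n)")
        if self.cA.shape != (n, n) or self.mA.shape != (n, n):
            raise ValueError("cA/mA must be (n, n)")
        if Fraction(self.alpha) >= 0:
            raise ValueError("alpha must be negative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        for c, name in ((self.cU, "cU"), (self.cP, "cP"), (self.cA, "cA")):
            if (c < 0).any():
                raise ValueError(f"{name} has negative entries")
        if not np.allclose(self.cU, self.cU.T):
            raise ValueError("cU must be symmetric")
        if not np.allclose(self.cA, self.cA.T):
            raise ValueError("cA must be symmetric")

    def copy(self) -> "ContactData":
        return ContactData(
            self.n, self.cU.copy(), self.cP.copy(), self.cA.copy(),
            self.mU.copy(), self.mP.copy(), self.mA.copy(),
            self.alpha, self.gamma,
        )


def _availability_masks(partition: LociPartition):
    """Masks of the entries the partition semantics define.

    cU: bead pairs of distinct unambiguous loci (all four homolog
    combinations); the same-locus entries (i, i), (i, n+i), (n+i, n+i) are
    self contacts and unavailable.  cP: phased bead of an unambiguous locus
    against an ambiguous locus.  cA: distinct ambiguous locus pairs.
    """
    n = partition.n
    U, A = partition.U, partition.A
    inU = np.zeros(n, dtype=bool)
    inU[U] = True
    inA = np.zeros(n, dtype=bool)
    inA[A] = True

    beadU = np.concatenate([inU, inU])  # bead-level indicator, length 2n
    mU = np.outer(beadU, beadU)
    locus = np.concatenate([np.arange(n), np.arange(n)])
    same_locus = locus[:, None] == locus[None, :]
    mU &= ~same_locus

    mP = np.outer(beadU, inA)
    mA = np.outer(inA, inA)
    np.fill_diagonal(mA, False)
    return mU, mP, mA


def contacts_from_structure(
    structure: Structure3D,
    partition: LociPartition,
    alpha: Fraction | float = Fraction(-2),
) -> ContactData:
    """Forward model: exact noiseless counts from bead coordinates.

    Unambiguous entries are single power-law terms ``d**alpha``, partially
    ambiguous entries are two-term sums, ambiguous entries four-term sums.
    Raises if any bead pair contributing a term coincides (the power law
    diverges) or if ``alpha >= 0``.
    """
    alpha = Fraction(alpha)
    if alpha >= 0:
        raise ValueError("the forward model requires a negative alpha")
    n = structure.n
    if partition.n != n:
        raise ValueError("partition size does not match structure")

    z = structure.z
    diff = z[:, None, :] - z[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)

    mU, mP, mA = _availability_masks(partition)

    # any bead-level pair feeding some available entry must be non-coincident
    contributing = mU.copy()
    for j in partition.A:
        contributing[:, [j, j + n]] |= mP[:, [j]]
        contributing[[j, j + n], :] |= mP[:, [j]].T
    for i in partition.A:
        for j in partition.A:
            if mA[i, j]:
                contributing[np.ix_([i, i + n], [j, j + n])] = True
    bad = contributing & (d2 <= 0.0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"coincident beads {i} and {j} contribute a contact term")

    with np.errstate(divide="ignore"):
        pw = np.where(d2 > 0, d2 ** (float(alpha) / 2.0), 0.0)

    cU = np.where(mU, pw, 0.0)
    cP = np.zeros((2 * n, n))
    cA = np.zeros((n, n))
    for j in partition.A:
        cP[:, j] = pw[:, j] + pw[:, j + n]
    cP = np.where(mP, cP, 0.0)
    for i in partition.A:
        cA[i, :] = pw[i, :n] + pw[i, n:] + pw[i + n, :n] + pw[i + n, n:]
    cA = np.where(mA, cA, 0.0)
    # the four-term sums accumulate in row order; mirror the upper triangle
    # so cA is symmetric to the last ulp
    cA = np.triu(cA, 1)
    cA = cA + cA.T

    return ContactData(n, cU, cP, cA, mU, mP, mA, alpha=alpha, gamma=1.0)


def add_noise(contacts: ContactData, epsilon: float, seed: int) -> ContactData:
    """Multiplicative noise: each available entry times (1 + delta),
    delta ~ Uniform(-epsilon, epsilon), independently per matrix.

    Stream order: one full (2n, 2n) draw for cU (upper triangle mirrored so
    cU stays symmetric; one draw per unordered pair), then a full (2n, n)
    draw for cP, then an (n, n) draw for cA (upper triangle mirrored).
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = contacts.copy()
    m = 2 * contacts.n

    dU = rng.uniform(-epsilon, epsilon, size=(m, m))
    dU = np.triu(dU, 1)
    dU = dU + dU.T
    dP = rng.uniform(-epsilon, epsilon, size=(m, contacts.n))
    dA = rng.uniform(-epsilon, epsilon, size=(contacts.n, contacts.n))
    dA = np.triu(dA, 1)
    dA = dA + dA.T

    out.cU = np.where(out.mU, out.cU * (1.0 + dU), out.cU)
    out.cP = np.where(out.mP, out.cP * (1.0 + dP), out.cP)
    out.cA = np.where(out.mA, out.cA * (1.0 + dA), out.cA)
    return out
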
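"""Exact symmetry breaking over per-locus homolog swaps.

Every earlier stage is blind to swapping (x_i, y_i) for an ambiguous locus
i.  Assuming homologous chromosomes occupy separate territories, the final
assignment minimizes the summed squared consecutive intra-homolog jumps

    sum_{i=1}^{n-1} ||x_i - x_{i+1}||^2 + ||y_i - y_{i+1}||^2

over the 2^|A| swap choices.  Writing s_i = +1 (keep) or -1 (swap) and
w_{i,i+1} = (x_i - y_i) . (x_{i+1} - y_{i+1}), the problem decouples into
maximizing sum w_{i,i+1} s_i s_{i+1} independently over each contiguous
chunk of ambiguous loci delimited by unambiguous ones, which a sign
recursion solves exactly: chunks with a free end propagate
s_{i+1} = sgn(w) s_i from their single fixed end; an interior chunk (both
ends fixed) may be forced to violate one link, and the optimal violated
link is the one with the smallest |w|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import LociPartition, Structure3D

__all__ = ["SignAssignment", "Chunk", "chunk_decomposition", "optimal_signs",
           "apply_signs", "swap_objective"]


def _sgn(v: float) -> int:
    """Sign with the deterministic convention sgn(0) = +1."""
    return -1 if v < 0 else 1


@dataclass(frozen=True)
class Chunk:
    start: int  # 0-based, inclusive
    stop: int  # inclusive
    kind: str  # "first" (free left end), "inner", "last" (free right end)


@dataclass
class SignAssignment:
    s: np.ndarray  # (n,) of +-1; +1 on U
    w: np.ndarray  # (n-1,) link inner products
    chunks: list[Chunk]
    objective: float = float("nan")


def chunk_decomposition(partition: LociPartition) -> list[Chunk]:
    """Maximal runs of ambiguous loci delimited by unambiguous ones.

    With U = (i_1, ..., i_L) and sentinels i_0 = first locus, i_{L+1} =
    last locus, the candidate chunks are the intervals [i_l, i_{l+1}];
    intervals containing no ambiguous locus are dropped.  A chunk whose
    left (right) boundary is not an unambiguous locus has a free end and is
    tagged "first" ("last"); with U empty the single chunk spans everything
    and is tagged "last" (free-start extension of the recursion).
    """
    n = partition.n
    U = partition.U
    if len(U) == 0:
        return [Chunk(0, n - 1, "last")] if n >= 1 else []
    bounds = np.concatenate([[0], U, [n - 1]])
    chunks: list[Chunk] = []
    Aset = set(partition.A.tolist())
    for a, b in zip(bounds[:-1], bounds[1:]):
        a, b = int(a), int(b)
        if not any(i in Aset for i in range(a, b + 1)):
            continue
        if a not in Aset and b not in Aset:
            kind = "inner"
        elif b in Aset and a not in Aset:
            kind = "last"
        elif a in Aset and b not in Aset:
            kind = "first"
        else:  # both ends ambiguous: U empty handled above, so impossible here
            kind = "last"
        chunks.append(Chunk(a, b, kind))
    return chunks


def link_products(xbar: np.ndarray, ybar: np.ndarray) -> np.ndarray:
    """w_{i,i+1} = (x_i - y_i) . (x_{i+1} - y_{i+1})."""
    v = np.asarray(xbar, float) - np.asarray(ybar, float)
    return np.einsum("ij,ij->i", v[:-1], v[1:])


def optimal_signs(xbar: np.ndarray, ybar: np.ndarray,
                  partition: LociPartition) -> SignAssignment:
    """Exact minimizer of the consecutive-jump objective over swap choices."""
    xbar = np.asarray(xbar, dtype=float)
    ybar = np.asarray(ybar, dtype=float)
    n = partition.n
    w = link_products(xbar, ybar)
    s = np.ones(n, dtype=int)
    chunks = chunk_decomposition(partition)
    for ch in chunks:
        a, b = ch.start, ch.stop
        if ch.kind == "last":
            # fixed (or conventional +1) left end, forward recursion
            for i in range(a, b):
                s[i + 1] = _sgn(w[i]) * s[i]
        elif ch.kind == "first":
            for i in range(b - 1, a - 1, -1):
                s[i] = _sgn(w[i]) * s[i + 1]
        else:  # inner: both ends fixed at +1; weakest link may be violated
            k = a + int(np.argmin(np.abs(w[a:b])))  # ties -> smallest index
            for i in range(a, k):
                s[i + 1] = _sgn(w[i]) * s[i]
            s[b] = 1
            for i in range(b - 1, k, -1):
                s[i] = _sgn(w[i]) * s[i + 1]
    s[partition.U] = 1
    assignment = SignAssignment(s=s, w=w, chunks=chunks)
    assignment.objective = swap_objective(xbar, ybar, s)
    return assignment


def swap_objective(xbar: np.ndarray, ybar: np.ndarray, s: np.ndarray) -> float:
    """Summed squared consecutive jumps of both homolog chains under s."""
    xbar = np.asarray(xbar, float)
    ybar = np.asarray(ybar, float)
    s = np.asarray(s)
    X = np.where((s == 1)[:, None], xbar, ybar)
    Y = np.where((s == 1)[:, None], ybar, xbar)
    dx = np.diff(X, axis=0)
    dy = np.diff(Y, axis=0)
    return float(np.einsum("ij,ij->", dx, dx) + np.einsum("ij,ij->", dy, dy))


def apply_signs(structure: Structure3D, signs: SignAssignment | np.ndarray) -> Structure3D:
    """Swap (x_i, y_i) wherever s_i = -1."""
    s = signs.s if isinstance(signs, SignAssignment) else np.asarray(signs)
    if len(s) != structure.n:
        raise ValueError("sign vector length must equal the number of loci")
    keep = (s == 1)[:, None]
    return Structure3D(
        np.where(keep, structure.x, structure.y),
        np.where(keep, structure.y, structure.x),
    )
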
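"""Computational identifiability certificates.

Three independent computations certify that the reconstruction problem is
well posed:

* the Jacobian of the fully ambiguous contact map (12 bead pairs, 66
  four-term inverse-square sums, 72 coordinates) has full rank 66 at a
  random rational configuration for alpha = -2 — computed in exact
  arithmetic;
* the 6x6 anchor matrix at the unit-cube configuration has nonzero
  determinant for alpha = -2 (the partial-ambiguity finiteness
  certificate);
* the generic root count of the six-anchor system (80) is bounded by the
  mixed volume of its Newton polytopes (1280), itself bounded by the
  Bezout number 4^6 = 4096.

Exact ranks use integer row clearing plus modular elimination: the rank of
an integer matrix over Z/p never exceeds its rank over Q, so full rank
modulo a prime is a proof of full rank; deficient modular rank falls back
to fraction-arithmetic Gaussian elimination.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

import numpy as np
import sympy as sp
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "AmbiguousMap",
    "UnitCubeMatrix",
    "random_rational_configuration",
    "ambiguous_jacobian_rank",
    "unit_cube_matrix",
    "generic_root_count",
    "mixed_volume_bound",
    "BEZOUT_BOUND",
]

BEZOUT_BOUND = 4**6

_PRIME = (1 << 61) - 1  # Mersenne prime for modular rank certificates


# ---------------------------------------------------------------------------
# exact linear algebra helpers

def _rank_mod_p(rows: list[list[int]], p: int = _PRIME) -> int:
    """Rank of an integer matrix over Z/p (lower-bounds the rank over Q)."""
    M = [[v % p for v in row] for row in rows]
    nrow = len(M)
    ncol = len(M[0]) if nrow else 0
    rank, r = 0, 0
    for c in range(ncol):
        piv = next((i for i in range(r, nrow) if M[i][c]), None)
        if piv is None:
            continue
        M[r], M[piv] = M[piv], M[r]
        inv = pow(M[r][c], p - 2, p)
        M[r] = [(v * inv) % p for v in M[r]]
        for i in range(nrow):
            if i != r and M[i][c]:
                f = M[i][c]
                M[i] = [(a - f * b) % p for a, b in zip(M[i], M[r])]
        r += 1
        rank += 1
        if r == nrow:
            break
    return rank


def _rank_exact_fractions(rows: list[list[Fraction]]) -> int:
    """Exact rank by Gaussian elimination over Q."""
    M = [list(row) for row in rows]
    nrow = len(M)
    ncol = len(M[0]) if nrow else 0
    rank, r = 0, 0
    for c in range(ncol):
        piv = next((i for i in range(r, nrow) if M[i][c] != 0), None)
        if piv is None:
            continue
        M[r], M[piv] = M[piv], M[r]
        pv = M[r][c]
        M[r] = [v / pv for v in M[r]]
        for i in range(r + 1, nrow):
            if M[i][c] != 0:
                f = M[i][c]
                M[i] = [a - f * b for a, b in zip(M[i], M[r])]
        r += 1
        rank += 1
        if r == nrow:
            break
    return rank


# ---------------------------------------------------------------------------
# the fully ambiguous contact map

@dataclass
class AmbiguousMap:
    """The 66-component map of a 12-pair configuration and its Jacobian."""

    configuration: np.ndarray  # (12, 2, 3) object array of Fractions or floats
    alpha: Fraction
    values: np.ndarray | None = None
    jacobian: np.ndarray | list | None = None


def random_rational_configuration(seed: int, numerator_span: int = 40,
                                  denominator: int = 7) -> np.ndarray:
    """12 random bead pairs with rational coordinates (object array of
    Fractions), suitable for the exact rank certificate."""
    rng = np.random.default_rng(seed)
    nums = rng.integers(-numerator_span, numerator_span + 1, size=(12, 2, 3))
    cfg = np.empty((12, 2, 3), dtype=object)
    for idx in np.ndindex(12, 2, 3):
        cfg[idx] = Fraction(int(nums[idx]), denominator)
    return cfg


def _as_pairs(config) -> np.ndarray:
    cfg = np.asarray(config, dtype=object)
    if cfg.shape == (24, 3):
        cfg = cfg.reshape(12, 2, 3)
    if cfg.shape != (12, 2, 3):
        raise ValueError("configuration must be 12 bead pairs in R^3")
    return cfg


def _jacobian_rows_exact(cfg: np.ndarray, alpha: Fraction):
    """Rows of the 66x72 Jacobian for even integer alpha, as exact Fractions.

    Each component (i < j) is the sum of Q(u)^(alpha/2) over the four
    cross-pair differences u; columns are ordered
    (x_i, y_i) blocks of three, i = 1..12.
    """
    half = alpha / 2
    if half.denominator != 1:
        raise ValueError("exact path requires an even integer alpha")
    m = int(half)
    rows = []
    for i, j in combinations(range(12), 2):
        row = [Fraction(0)] * 72
        for hi in range(2):  # homolog of locus i: 0 -> x_i, 1 -> y_i
            for hj in range(2):
                u = [cfg[i, hi, k] - cfg[j, hj, k] for k in range(3)]
                Q = sum(v * v for v in u)
                if Q == 0:
                    raise ValueError(
                        f"coincident beads at loci ({i}, {j}); map undefined"
                    )
                coef = Fraction(m) * Q ** (m - 1)  # d Q^m / d Q
                for k in range(3):
                    ci = 6 * i + 3 * hi + k
                    cj = 6 * j + 3 * hj + k
                    row[ci] += coef * 2 * u[k]
                    row[cj] -= coef * 2 * u[k]
        rows.append(row)
    return rows


def _jacobian_numeric(cfg_f: np.ndarray, alpha: float) -> np.ndarray:
    half = alpha / 2.0
    rows = []
    for i, j in combinations(range(12), 2):
        row = np.zeros(72)
        for hi in range(2):
            for hj in range(2):
                u = cfg_f[i, hi] - cfg_f[j, hj]
                Q = float(u @ u)
                if Q <= 0:
                    raise ValueError(f"coincident beads at loci ({i}, {j})")
                coef = half * Q ** (half - 1.0)
                g = coef * 2.0 * u
                row[6 * i + 3 * hi: 6 * i + 3 * hi + 3] += g
                row[6 * j + 3 * hj: 6 * j + 3 * hj + 3] -= g
        rows.append(row)
    return np.array(rows)


def ambiguous_jacobian_rank(config, alpha: Fraction | float = Fraction(-2)) -> int:
    """Rank of the 66x72 Jacobian of the fully ambiguous contact map.

    For rational configurations with even integer alpha the rank is exact:
    each row is cleared to integers by a nonzero rational scaling, full
    rank is certified modulo a large prime, and a deficient modular rank
    triggers exact fraction elimination.  Other inputs use a numerical SVD
    with a relative threshold of 1e-8.
    """
    cfg = _as_pairs(config)
    alpha_f = Fraction(alpha) if not isinstance(alpha, float) else None
    rational = all(isinstance(v, (Fraction, int, np.integer))
                   for v in cfg.ravel())
    if rational and alpha_f is not None and (alpha_f / 2).denominator == 1:
        rows = _jacobian_rows_exact(cfg, alpha_f)
        int_rows = []
        for row in rows:
            den = np.lcm.reduce([f.denominator for f in row if f != 0] or [1])
            int_rows.append([int(f * den) for f in row])
        r = _rank_mod_p(int_rows)
        if r == min(len(int_rows), 72):
            return r  # full modular rank proves full rank over Q
        return _rank_exact_fractions(rows)
    cfg_f = cfg.astype(float)
    Jm = _jacobian_numeric(cfg_f, float(alpha))
    s = np.linalg.svd(Jm, compute_uv=False)
    return int(np.sum(s > 1e-8 * s[0]))


# ---------------------------------------------------------------------------
# the unit-cube anchor matrix

_CUBE_X = (0, 0, 0)
_CUBE_Y = (1, 1, 1)
# the six cube vertices other than x* and y*, in anchor order a..f
_CUBE_ANCHORS = ((1, 0, 0), (0, 1, 0), (0, 0, 1), (0, 1, 1), (1, 0, 1), (1, 1, 0))


@dataclass
class UnitCubeMatrix:
    M: sp.Matrix
    beta: Fraction
    determinant: sp.Expr


def unit_cube_matrix(alpha: Fraction | int = Fraction(-2)) -> UnitCubeMatrix:
    """The 6x6 anchor matrix at the unit-cube configuration.

    Row t is [||x*-t||^(alpha-2) (x*-t), ||y*-t||^(alpha-2) (y*-t)] with
    x* = (0,0,0), y* = (1,1,1) and the six remaining cube vertices as
    anchors (trivial roots of unity).  Its determinant is nonzero for
    alpha = -2, which is the finiteness certificate for the six-anchor
    system.
    """
    alpha = Fraction(alpha)
    if alpha >= 0:
        raise ValueError("alpha must be negative")
    beta = alpha - 2
    beta_sp = sp.Rational(beta.numerator, beta.denominator)
    x = sp.Matrix(_CUBE_X)
    y = sp.Matrix(_CUBE_Y)
    rows = []
    for t in _CUBE_ANCHORS:
        tv = sp.Matrix(t)
        dx = x - tv
        dy = y - tv
        nx = sp.sqrt(dx.dot(dx)) ** beta_sp
        ny = sp.sqrt(dy.dot(dy)) ** beta_sp
        rows.append(list(nx * dx.T) + list(ny * dy.T))
    M = sp.Matrix(rows)
    det = sp.simplify(M.det())
    return UnitCubeMatrix(M=M, beta=beta, determinant=det)


# ---------------------------------------------------------------------------
# root counts and polyhedral bounds

def generic_root_count(seed: int = 1):
    """Solve the six-anchor system at generic complex parameters and report
    (solution count, swap-orbit count) plus stabilization evidence."""
    from .polysolve import solve_phase1

    sols = solve_phase1(seed)
    return len(sols.solutions), sols.orbit_count, {
        "monodromy_loops": sols.monodromy_loops,
        "stabilized": sols.stabilized,
        "max_residual": float(sols.residuals.max()),
    }


def _newton_polytope_support() -> list[np.ndarray]:
    """Exponent supports of the six denominator-cleared quartics, derived
    symbolically at generic rational parameters."""
    xs = sp.symbols("x1 x2 x3 y1 y2 y3")
    supports = []
    base = [sp.Rational(p, q) for p, q in
            ((3, 7), (-2, 5), (5, 11), (1, 3), (-4, 9), (7, 13))]
    for t_idx in range(6):
        t = [base[(t_idx + k) % 6] + t_idx for k in range(3)]
        c = sp.Rational(2 * t_idx + 3, 2 * t_idx + 5)
        qx = sum((xs[k] - t[k]) ** 2 for k in range(3))
        qy = sum((xs[3 + k] - t[k]) ** 2 for k in range(3))
        poly = sp.Poly(sp.expand(qx + qy - c * qx * qy), *xs)
        supports.append(np.array(poly.monoms(), dtype=float))
    return supports


def _hull_reduce(points: np.ndarray) -> np.ndarray:
    points = np.unique(points, axis=0)
    if len(points) <= 7:
        return points
    try:
        hull = ConvexHull(points)
        return points[hull.vertices]
    except QhullError:
        return points  # lower-dimensional set: keep as is


def _minkowski_sum(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    pts = (A[:, None, :] + B[None, :, :]).reshape(-1, A.shape[1])
    return _hull_reduce(pts)


def _volume6(points: np.ndarray) -> float:
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 6:
        return 0.0
    return float(ConvexHull(points).volume)


def mixed_volume_bound() -> int:
    """Mixed volume of the six Newton polytopes of the anchor system.

    Computed by the inclusion-exclusion identity
    MV(P_1, ..., P_6) = sum over nonempty S of (-1)^(6-|S|) Vol6(sum_{i in S} P_i)
    over Minkowski sums of the support hulls; with the normalization
    MV(P, ..., P) = 6! Vol(P).  Upper-bounds the generic root count
    (Bernstein) and is itself bounded by the Bezout number 4^6.
    """
    supports = [_hull_reduce(s) for s in _newton_polytope_support()]
    total = 0.0
    for r in range(1, 7):
        sign = (-1) ** (6 - r)
        for S in combinations(range(6), r):
            acc = supports[S[0]]
            for i in S[1:]:
                acc = _minkowski_sum(acc, supports[i])
            total += sign * _volume6(acc)
    return int(round(total))
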
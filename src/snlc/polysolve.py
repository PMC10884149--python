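"""Six-anchor polynomial systems and their homotopy-continuation solution.

An ambiguous bead pair (x, y) in R^3 interacts with a chosen unambiguous
bead t through the partially ambiguous count ``c_t = ||x-t||^-2 +
||y-t||^-2``.  Clearing denominators for six anchors a, ..., f gives the
square polynomial system

    ||x-t||^2 + ||y-t||^2 = c_t * ||x-t||^2 * ||y-t||^2,   t = a, ..., f,

six quartics in the six unknowns (x1, x2, x3, y1, y2, y3), symmetric under
the swap (x, y) -> (y, x).  At generic (complex) parameters it has 80
finite nonsingular solutions, i.e. 40 swap orbits.

The solver follows the classical two-phase scheme:

* phase 1 solves the system once at random complex parameters.  The start
  set is populated by monodromy: a single planted solution is carried
  around random loops in parameter space until the solution count is
  stable, with the swap symmetry doubling every discovery.
* phase 2 is a straight-line parameter homotopy (with a random complex
  "gamma-trick" bend so the real target is approached from generic complex
  directions) tracking one representative per swap orbit — 40 paths — and
  reconstituting the orbit mates by applying the swap.

Path tracking is an adaptive-step predictor-corrector in complex
arithmetic: a 4th-order Runge-Kutta predictor on the Davidenko equation
dz/dtau = -J^-1 dF/dtau followed by Newton correction, with step halving on
corrector failure and plain Newton polishing at the endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as iter_product

import numpy as np

from .model import ContactData, LociPartition

__all__ = [
    "AnchorSystem",
    "SolutionSet",
    "solve_phase1",
    "solve_phase2",
    "approximately_real",
    "consensus_estimate",
    "estimate_ambiguous_pair",
    "get_phase1",
    "swap_xy",
]

_SWAP = np.array([3, 4, 5, 0, 1, 2])

# generic root count of the six-anchor system (certified by phase-1 runs and
# bounded above by the mixed volume 1280 and the Bezout number 4096)
GENERIC_ROOT_COUNT = 80


def swap_xy(z: np.ndarray) -> np.ndarray:
    """The symmetry (x, y) -> (y, x) on points of C^6 (rows)."""
    return np.asarray(z)[..., _SWAP]


@dataclass
class AnchorSystem:
    """A six-anchor instance: anchor coordinates and their counts."""

    anchors: np.ndarray  # (6, 3)
    counts: np.ndarray  # (6,)

    def __post_init__(self) -> None:
        self.anchors = np.asarray(self.anchors)
        self.counts = np.asarray(self.counts)
        if self.anchors.shape != (6, 3) or self.counts.shape != (6,):
            raise ValueError("need six anchors and six counts")
        d = self.anchors[:, None, :] - self.anchors[None, :, :]
        dist = np.sqrt(np.abs(np.einsum("ijk,ijk->ij", d, d.conj())))
        if (dist + np.eye(6) * 1e9 < 1e-12).any():
            raise ValueError("anchors must be pairwise distinct")
        if not np.iscomplexobj(self.counts) and (self.counts.real <= 0).any():
            raise ValueError("counts must be positive")


@dataclass
class SolutionSet:
    """Solutions of one six-anchor system together with its parameters."""

    anchors: np.ndarray
    counts: np.ndarray
    solutions: np.ndarray  # (k, 6) complex
    residuals: np.ndarray  # (k,) relative residuals
    n_paths_tracked: int = 0
    n_paths_failed: int = 0
    monodromy_loops: int = 0
    stabilized: bool = False

    def orbit_representatives(self) -> np.ndarray:
        """One solution per swap orbit (the lexicographically smaller mate)."""
        reps = []
        used = np.zeros(len(self.solutions), dtype=bool)
        sols = self.solutions
        for i, z in enumerate(sols):
            if used[i]:
                continue
            used[i] = True
            zs = swap_xy(z)
            d = np.abs(sols - zs[None]).max(axis=1)
            j = int(np.argmin(d))
            if d[j] < 1e-6 * (1.0 + np.abs(z).max()) and not used[j]:
                used[j] = True
            reps.append(z)
        return np.array(reps)

    @property
    def orbit_count(self) -> int:
        return len(self.orbit_representatives())


# ---------------------------------------------------------------------------
# system evaluation (batched over solutions)

def _unpack(p: np.ndarray):
    """Split a parameter vector (..., 24) into anchors (..., 6, 3) and counts."""
    p = np.asarray(p)
    return p[..., :18].reshape(p.shape[:-1] + (6, 3)), p[..., 18:]


def _eval(z, anchors, c, da=None, dc=None):
    """F (B,6), J (B,6,6), scale (B,6), and optionally dF/dtau (B,6).

    ``anchors``/``c`` may be shared ((6,3)/(6,)) or per path
    ((B,6,3)/(B,6)); parameter velocities ``da``/``dc`` likewise.
    """
    x = z[:, None, :3]
    y = z[:, None, 3:]
    if anchors.ndim == 2:
        anchors = anchors[None]
    if c.ndim == 1:
        c = c[None]
    dx = x - anchors  # (B, 6, 3)
    dy = y - anchors
    qx = (dx * dx).sum(-1)
    qy = (dy * dy).sum(-1)
    cxy = c * qx * qy
    F = qx + qy - cxy
    scale = 1.0 + np.abs(qx) + np.abs(qy) + np.abs(cxy)
    gx = 1.0 - c * qy  # d f_t / d qx
    gy = 1.0 - c * qx
    J = np.empty(z.shape[:1] + (6, 6), dtype=complex)
    J[..., :3] = 2.0 * dx * gx[..., None]
    J[..., 3:] = 2.0 * dy * gy[..., None]
    if da is None:
        return F, J, scale
    if da.ndim == 2:
        da = da[None]
    if dc.ndim == 1:
        dc = dc[None]
    Ft = (
        -2.0 * gx * (dx * da).sum(-1)
        - 2.0 * gy * (dy * da).sum(-1)
        - qx * qy * dc
    )
    return F, J, scale, Ft


def _solve_lin(J, rhs):
    """Batched 6x6 solve; singular members fall back to least squares."""
    try:
        return np.linalg.solve(J, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        out = np.empty_like(rhs)
        for i in range(len(J)):
            try:
                out[i] = np.linalg.solve(J[i], rhs[i])
            except np.linalg.LinAlgError:
                out[i] = np.linalg.lstsq(J[i], rhs[i], rcond=None)[0]
        return out


class _Segment:
    """Parameter path p(tau) from p0 to p1 with a complex gamma bend."""

    def __init__(self, p0: np.ndarray, p1: np.ndarray, gamma: complex):
        self.p0, self.p1, self.gamma = p0, p1, gamma

    def at(self, tau: float):
        g = self.gamma
        w = (1.0 - tau) * g + tau
        num = (1.0 - tau) * g * self.p0 + tau * self.p1
        p = num / w
        dp = ((self.p1 - g * self.p0) * w - num * (1.0 - g)) / w**2
        return p, dp


def _newton(z, anchors, c, iters=3, tol=1e-9):
    """Newton correction at fixed parameters; returns z, ok mask, residual."""
    res = None
    updated = False
    for _ in range(iters):
        F, J, scale = _eval(z, anchors, c)
        res = (np.abs(F) / scale).max(axis=1)
        updated = False
        if (res < tol).all():
            break
        dz = _solve_lin(J, -F)
        z = z + dz
        updated = True
    if updated:
        F, _, scale = _eval(z, anchors, c)
        res = (np.abs(F) / scale).max(axis=1)
    finite = np.isfinite(z).all(axis=1) & (np.abs(z).max(axis=1) < 1e8)
    return z, (res < tol) & finite, res


def _seg_params(seg, tau, rows):
    """Parameters and velocities at tau, restricted to the given path rows
    when the segment carries per-path targets."""
    p, dp = seg.at(tau)
    if p.ndim == 2 and rows is not None:
        p, dp = p[rows], dp[rows]
    return p, dp


def _rk4_predict(z, seg, tau, h, rows=None):
    def vel(zz, tt):
        p, dp = _seg_params(seg, tt, rows)
        a, c = _unpack(p)
        da, dc = _unpack(dp)
        F, J, _, Ft = _eval(zz, a, c, da, dc)
        return _solve_lin(J, -Ft)

    k1 = vel(z, tau)
    k2 = vel(z + 0.5 * h * k1, tau + 0.5 * h)
    k3 = vel(z + 0.5 * h * k2, tau + 0.5 * h)
    k4 = vel(z + h * k3, tau + h)
    return z + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def _track(z0, seg, tau0=0.0, tol=1e-8, h0=0.1, hmin=1e-12, hmax=0.4,
           max_steps=4000):
    """Track a batch of paths along ``seg`` from tau0 to 1.

    All paths share an adaptive step; paths that keep failing the corrector
    while the rest advance are re-tracked individually.  Returns the
    endpoint array and a success mask.
    """
    z = np.array(z0, dtype=complex)
    B = len(z)
    ok_final = np.zeros(B, dtype=bool)
    active = np.arange(B)
    tau, h, consec, steps = tau0, h0, 0, 0
    stragglers: list[tuple[int, float, np.ndarray]] = []

    while len(active) and tau < 1.0 - 1e-14 and steps < max_steps:
        steps += 1
        hstep = min(h, 1.0 - tau)
        zp = _rk4_predict(z[active], seg, tau, hstep, rows=active)
        p, _ = _seg_params(seg, tau + hstep, active)
        a, c = _unpack(p)
        zc, ok, _ = _newton(zp, a, c, iters=3, tol=tol)
        if ok.all():
            z[active] = zc
            tau += hstep
            h = min(h * 1.7, hmax)
            consec = 0
        elif consec < 10 and hstep * 0.5 >= hmin:
            h = hstep * 0.5
            consec += 1
        else:
            for i in active[~ok]:
                stragglers.append((int(i), tau, z[i].copy()))
            z[active[ok]] = zc[ok]
            active = active[ok]
            tau += hstep
            consec = 0

    if tau >= 1.0 - 1e-14:
        ok_final[active] = True
    else:  # ran out of steps
        for i in active:
            stragglers.append((int(i), tau, z[i].copy()))

    for i, t0, zi in stragglers:
        zz, good = _track_single(zi, seg, t0, tol, hmin, row=i)
        if good:
            z[i] = zz
            ok_final[i] = True
    return z, ok_final


def _track_single(z, seg, tau0, tol, hmin, max_steps=6000, row=None):
    rows = None if row is None else np.array([row])
    z = z[None].copy()
    tau, h, steps = tau0, 0.02, 0
    while tau < 1.0 - 1e-14 and steps < max_steps:
        steps += 1
        hstep = min(h, 1.0 - tau)
        zp = _rk4_predict(z, seg, tau, hstep, rows=rows)
        p, _ = _seg_params(seg, tau + hstep, rows)
        a, c = _unpack(p)
        zc, ok, _ = _newton(zp, a, c, iters=4, tol=tol)
        if ok[0]:
            z = zc
            tau += hstep
            h = min(h * 1.7, 0.3)
        else:
            h = hstep * 0.5
            if h < hmin:
                return z[0], False
    return z[0], tau >= 1.0 - 1e-14


# ---------------------------------------------------------------------------
# deduplication and certification

def _dedup(sols: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    if len(sols) == 0:
        return sols.reshape(0, 6)
    kept: list[np.ndarray] = []
    for z in sols:
        scale = 1.0 + np.abs(z).max()
        if all(np.abs(z - k).max() >= tol * scale for k in kept):
            kept.append(z)
    return np.array(kept)


def _polish_and_certify(sols, anchors, c, tol=1e-10):
    """Newton-polish candidate endpoints and keep certified regular solutions."""
    if len(sols) == 0:
        return sols.reshape(0, 6), np.zeros(0)
    z, ok, res = _newton(np.asarray(sols, dtype=complex), anchors, c,
                         iters=6, tol=tol)
    return z[ok], res[ok]


# ---------------------------------------------------------------------------
# phase 1: monodromy population at random complex parameters

def _crandn(rng, *shape):
    return (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2)


def _counts_for(z: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Counts making z an exact solution: c_t = (qx+qy)/(qx*qy)."""
    dx = z[:3][None] - anchors
    dy = z[3:][None] - anchors
    qx = np.einsum("tk,tk->t", dx, dx)
    qy = np.einsum("tk,tk->t", dy, dy)
    return (qx + qy) / (qx * qy)


def solve_phase1(seed: int, max_loops: int = 80, stable_loops: int = 3,
                 min_loops: int = 8) -> SolutionSet:
    """Solve the system at random complex parameters by monodromy.

    A solution (x*, y*) is planted, the matching counts computed, and random
    triangular loops in the 24-dimensional parameter space are traversed
    until the deduplicated solution count has not grown for
    ``stable_loops`` consecutive loops.  Generic parameters yield 80
    solutions in 40 swap orbits.
    """
    rng = np.random.default_rng(seed)
    anchors = _crandn(rng, 6, 3)
    zstar = _crandn(rng, 6)
    c = _counts_for(zstar, anchors)
    p0 = np.concatenate([anchors.ravel(), c])

    sols = _dedup(np.vstack([zstar[None], swap_xy(zstar)[None]]))
    tracked = failed = 0
    no_growth = 0
    loops = 0
    while loops < max_loops and (no_growth < stable_loops or loops < min_loops):
        loops += 1
        p1 = _crandn(rng, 24) * np.abs(p0).mean()
        p2 = _crandn(rng, 24) * np.abs(p0).mean()
        z = sols.copy()
        alive = np.ones(len(z), dtype=bool)
        for a, b in ((p0, p1), (p1, p2), (p2, p0)):
            gamma = np.exp(1j * rng.uniform(0.15, np.pi - 0.15))
            z[alive], ok = _track(z[alive], _Segment(a, b, gamma))
            tracked += int(alive.sum())
            failed += int((~ok).sum())
            idx = np.where(alive)[0]
            alive[idx[~ok]] = False
        new, _ = _polish_and_certify(z[alive], anchors, c, tol=1e-9)
        before = len(sols)
        sols = _dedup(np.vstack([sols, new, swap_xy(new)]))
        no_growth = no_growth + 1 if len(sols) == before else 0

    if tracked and failed / tracked > 0.2:
        raise RuntimeError(
            f"path-tracking failure rate {failed/tracked:.0%} exceeds 20%; "
            "retry solve_phase1 with a different seed"
        )
    sols, res = _polish_and_certify(sols, anchors, c, tol=1e-9)
    sols = _dedup(sols)
    _, _, scale = _eval(sols, anchors, c)
    F, _, scale = _eval(sols, anchors, c)
    res = (np.abs(F) / scale).max(axis=1)
    return SolutionSet(anchors, c, sols, res, n_paths_tracked=tracked,
                       n_paths_failed=failed, monodromy_loops=loops,
                       stabilized=no_growth >= stable_loops)


_PHASE1_CACHE: dict[int, SolutionSet] = {}


def get_phase1(seed: int = 2023) -> SolutionSet:
    """Process-wide cached phase-1 start system keyed by the homotopy seed."""
    if seed not in _PHASE1_CACHE:
        _PHASE1_CACHE[seed] = solve_phase1(seed)
    return _PHASE1_CACHE[seed]


_PHASE1_FORMAT_VERSION = 1


def save_phase1(start: SolutionSet, path, seed: int) -> None:
    """Serialize a phase-1 start system to a versioned JSON text file."""
    import json
    from pathlib import Path

    def c2l(a):
        a = np.asarray(a, dtype=complex)
        return [a.real.ravel().tolist(), a.imag.ravel().tolist(), list(a.shape)]

    doc = {
        "format_version": _PHASE1_FORMAT_VERSION,
        "seed": int(seed),
        "anchors": c2l(start.anchors),
        "counts": c2l(start.counts),
        "solutions": c2l(start.solutions),
        "residuals": np.asarray(start.residuals).tolist(),
        "monodromy_loops": start.monodromy_loops,
        "stabilized": start.stabilized,
    }
    Path(path).write_text(json.dumps(doc) + "\n")


def load_phase1(path) -> tuple[SolutionSet, int]:
    """Load a serialized phase-1 start system; returns (start, seed)."""
    import json
    from pathlib import Path

    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != _PHASE1_FORMAT_VERSION:
        raise ValueError("unsupported phase-1 cache format version")

    def l2c(entry):
        re, im, shape = entry
        return (np.asarray(re) + 1j * np.asarray(im)).reshape(shape)

    start = SolutionSet(
        anchors=l2c(doc["anchors"]),
        counts=l2c(doc["counts"]),
        solutions=l2c(doc["solutions"]),
        residuals=np.asarray(doc["residuals"]),
        monodromy_loops=int(doc["monodromy_loops"]),
        stabilized=bool(doc["stabilized"]),
    )
    return start, int(doc["seed"])


# ---------------------------------------------------------------------------
# phase 2: parameter homotopy to the target system

def _pack(anchors, counts) -> np.ndarray:
    return np.concatenate([
        np.asarray(anchors, dtype=complex).ravel(),
        np.asarray(counts, dtype=complex),
    ])


def solve_phase2_many(start: SolutionSet, targets: list[AnchorSystem],
                      seed: int | None = None) -> list[SolutionSet | None]:
    """Track the start solutions to several target systems in one batch.

    One representative per swap orbit is tracked for every target (40 paths
    each for the generic 80-solution start), all stacked into a single
    batched continuation run; orbit mates are reconstituted by the swap.
    Targets for which every path fails yield ``None``.
    """
    rng = np.random.default_rng(seed)
    p0 = np.concatenate([start.anchors.ravel(), start.counts])
    reps = start.orbit_representatives()
    R = len(reps)
    K = len(targets)
    p1 = np.repeat(np.stack([_pack(t.anchors, t.counts) for t in targets]),
                   R, axis=0)  # (K*R, 24)
    z0 = np.tile(reps, (K, 1))
    gamma = np.exp(1j * rng.uniform(0.15, np.pi - 0.15))
    z, ok = _track(z0, _Segment(p0, p1, gamma))

    out: list[SolutionSet | None] = []
    for k, target in enumerate(targets):
        sel = slice(k * R, (k + 1) * R)
        anchors_t = np.asarray(target.anchors, dtype=complex)
        counts_t = np.asarray(target.counts, dtype=complex)
        good, _ = _polish_and_certify(z[sel][ok[sel]], anchors_t, counts_t,
                                      tol=1e-8)
        sols = _dedup(np.vstack([good, swap_xy(good)]) if len(good) else good)
        if len(sols) == 0:
            out.append(None)
            continue
        F, _, scale = _eval(sols, anchors_t, counts_t)
        res = (np.abs(F) / scale).max(axis=1)
        out.append(SolutionSet(anchors_t, counts_t, sols, res,
                               n_paths_tracked=R,
                               n_paths_failed=int((~ok[sel]).sum())))
    return out


def solve_phase2(start: SolutionSet, target: AnchorSystem,
                 seed: int | None = None) -> SolutionSet:
    """Track the start solutions to the target parameters.

    Only one representative per swap orbit is tracked (40 paths for the
    generic 80-solution start); the orbit mates are reconstituted by the
    swap.  Divergent or singular endpoints are discarded.
    """
    p0 = np.concatenate([start.anchors.ravel(), start.counts])
    if np.abs(_pack(target.anchors, target.counts) - p0).max() < 1e-14:
        return SolutionSet(start.anchors, start.counts, start.solutions.copy(),
                           start.residuals.copy(), n_paths_tracked=0)
    result = solve_phase2_many(start, [target], seed=seed)[0]
    if result is None:
        raise RuntimeError("all homotopy paths failed for the target system")
    return result


def approximately_real(solutions: SolutionSet | np.ndarray,
                       tol: float = 0.15) -> np.ndarray:
    """Real parts of the solutions whose imaginary max-norm is below tol."""
    sols = solutions.solutions if isinstance(solutions, SolutionSet) else np.asarray(solutions)
    if len(sols) == 0:
        return np.zeros((0, 6))
    keep = np.abs(sols.imag).max(axis=1) < tol
    return sols.real[keep]


def consensus_estimate(candidate_sets: list[np.ndarray],
                       max_product: int = 10**6) -> np.ndarray:
    """Most consistent candidate across the N solution sets.

    Each set is augmented with the swap image of each of its candidates;
    the product of the sets is searched exhaustively for the tuple
    (w_1, ..., w_N) minimizing the summed deviation from the tuple mean,
    and that mean is returned.
    """
    if len(candidate_sets) < 2:
        raise ValueError("need at least two candidate sets")
    aug = []
    for s in candidate_sets:
        s = np.asarray(s, dtype=float).reshape(-1, 6)
        if len(s) == 0:
            raise ValueError("empty candidate set")
        aug.append(_dedup(np.vstack([s, swap_xy(s)]).astype(complex)).real)
    total = int(np.prod([len(s) for s in aug]))
    if total > max_product:
        raise ValueError(
            f"candidate product size {total} exceeds {max_product}; prune candidates"
        )
    best_val, best_mean = np.inf, None
    for combo in iter_product(*aug):
        W = np.array(combo)
        mean = W.mean(axis=0)
        val = float(np.linalg.norm(W - mean[None], axis=1).sum())
        if val < best_val:
            best_val, best_mean = val, mean
    return best_mean


def _fallback_estimate(locus: int, partition: LociPartition,
                       unamb_coords: np.ndarray) -> np.ndarray:
    """Average of the bead midpoints of the genomically nearest unambiguous
    loci (one on each side where available)."""
    U = partition.U
    nu = len(U)
    mid = 0.5 * (unamb_coords[:nu] + unamb_coords[nu:])
    left = U[U < locus]
    right = U[U > locus]
    picks = []
    if len(left):
        picks.append(mid[np.searchsorted(U, left[-1])])
    if len(right):
        picks.append(mid[np.searchsorted(U, right[0])])
    if not picks:
        raise ValueError("no unambiguous loci available for fallback")
    p = np.mean(picks, axis=0)
    return np.concatenate([p, p])


def estimate_ambiguous_pair(
    locus: int,
    unamb_coords: np.ndarray,
    contacts: ContactData,
    partition: LociPartition,
    N: int = 5,
    pool: int = 20,
    max_attempts: int = 100,
    tol: float = 0.15,
    seed: int | None = None,
    phase1_seed: int = 2023,
) -> tuple[np.ndarray, np.ndarray, str]:
    """Estimate one ambiguous bead pair by N-draw consensus.

    Anchors are drawn from the ``pool`` unambiguous *beads* with the highest
    partially ambiguous count to this locus (both homolog beads of an
    unambiguous locus are eligible; counts come from the corresponding rows
    of cP).  Each six-anchor system is solved by a phase-2 parameter
    homotopy from the cached phase-1 start; draws yielding no approximately
    real solution are redrawn, up to ``max_attempts`` draws in total.  If
    fewer than two nonempty candidate sets are found, the genomic-neighbor
    fallback estimate is returned with flag ``"fallback"``.

    Returns ``(x, y, flag)`` with flag in {"solved", "fallback"}.
    """
    if len(partition.U) < 6:
        raise ValueError("need at least six unambiguous loci")
    n = contacts.n
    nu = len(partition.U)
    beads = np.concatenate([partition.U, partition.U + n])  # global bead ids
    counts = contacts.cP[beads, locus]
    avail = contacts.mP[beads, locus] & (counts > 0)
    cand = np.where(avail)[0]
    if len(cand) < 6:
        raise ValueError("fewer than six usable anchor beads for this locus")
    order = cand[np.argsort(counts[cand])[::-1]]
    pool_idx = order[: min(pool, len(order))]
    coords = np.asarray(unamb_coords, dtype=float)
    if coords.shape != (2 * nu, 3):
        raise ValueError("unamb_coords must be (2|U|, 3)")

    rng = np.random.default_rng(seed)
    start = get_phase1(phase1_seed)
    sets: list[np.ndarray] = []
    attempts_left = max_attempts + N
    while attempts_left > 0 and len(sets) < N:
        attempts_left -= 1
        pick = rng.choice(pool_idx, size=6, replace=False)
        anchors = coords[pick]
        if np.linalg.matrix_rank(anchors - anchors.mean(axis=0)) < 3:
            continue  # coplanar anchor draw, retry
        try:
            system = AnchorSystem(anchors, counts[pick])
            sol = solve_phase2(start, system, seed=int(rng.integers(2**31)))
        except (RuntimeError, ValueError):
            continue
        reals = approximately_real(sol, tol=tol)
        if len(reals):
            sets.append(reals)
    if len(sets) < 2:
        est = _fallback_estimate(locus, partition, coords)
        return est[:3], est[3:], "fallback"
    est = consensus_estimate(sets)
    return est[:3], est[3:], "solved"
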
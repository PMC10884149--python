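"""Global refinement of the ambiguous bead coordinates.

The per-locus polynomial estimates use only six anchors at a time; this
stage re-fits all ambiguous pairs jointly against every available partially
ambiguous count, keeping the unambiguous coordinates fixed:

    min over {x_j, y_j}_{j in A} of
      sum_{i in U, j in A}  (cP[i, j]   - 1/||x_i-x_j||^2 - 1/||x_i-y_j||^2)^2
                          + (cP[i+n, j] - 1/||y_i-x_j||^2 - 1/||y_i-y_j||^2)^2

minimized with a quasi-Newton method (L-BFGS) from the polynomial-stage
initialization.  The objective is invariant under swapping (x_j, y_j) for
any ambiguous j — the symmetry broken by the final clustering stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .model import ContactData, LociPartition

__all__ = ["RefineProblem", "objective_and_gradient", "local_refine"]

_DMIN2 = 1e-18  # squared-distance floor below which a term is singular


@dataclass
class RefineProblem:
    """Fixed unambiguous coordinates, cP data, and optimizer settings."""

    unamb_coords: np.ndarray  # (2|U|, 3): [x_i for i in U] + [y_i for i in U]
    contacts: ContactData
    partition: LociPartition
    grad_tol: float = 1e-6
    max_iter: int = 500

    def __post_init__(self) -> None:
        nu = len(self.partition.U)
        self.unamb_coords = np.asarray(self.unamb_coords, dtype=float)
        if self.unamb_coords.shape != (2 * nu, 3):
            raise ValueError("unamb_coords must be (2|U|, 3)")
        n = self.contacts.n
        U, A = self.partition.U, self.partition.A
        # term table: anchor bead coordinate row, ambiguous locus slot, count
        anchors = np.vstack([self.unamb_coords[:nu], self.unamb_coords[nu:]])
        rows = np.concatenate([U, U + n])
        self._anchor_xyz = anchors
        self._slot = {int(j): k for k, j in enumerate(A)}
        mask = self.contacts.mP[np.ix_(rows, A)]
        self._ai, self._aj = np.nonzero(mask)  # anchor row index, A slot
        self._cP = self.contacts.cP[np.ix_(rows, A)][self._ai, self._aj]

    @property
    def n_ambiguous(self) -> int:
        return len(self.partition.A)


def objective_and_gradient(problem: RefineProblem,
                           ambiguous_coords: np.ndarray):
    """Value and analytic gradient of the residual objective.

    ``ambiguous_coords`` is (2|A|, 3): x rows then y rows, in the order of
    ``partition.A``.  Raises if a contributing bead pair coincides.
    """
    na = problem.n_ambiguous
    Z = np.asarray(ambiguous_coords, dtype=float).reshape(2 * na, 3)
    X, Y = Z[:na], Z[na:]
    ai, aj = problem._ai, problem._aj
    T = problem._anchor_xyz[ai]  # anchor coordinates per term
    dx = T - X[aj]
    dy = T - Y[aj]
    qx = np.einsum("ij,ij->i", dx, dx)
    qy = np.einsum("ij,ij->i", dy, dy)
    if (qx < _DMIN2).any() or (qy < _DMIN2).any():
        bad = int(np.argmax((qx < _DMIN2) | (qy < _DMIN2)))
        raise ValueError(
            f"coincident beads in term (anchor row {ai[bad]}, ambiguous slot {aj[bad]})"
        )
    res = problem._cP - 1.0 / qx - 1.0 / qy
    value = float(np.sum(res**2))
    # d value / d x_j = sum_terms 2*res * (-2 (x_j - t) / qx^2)
    gx = np.zeros_like(X)
    gy = np.zeros_like(Y)
    cx = (2.0 * res / qx**2)[:, None] * (-2.0 * dx)  # dx = t - x
    cy = (2.0 * res / qy**2)[:, None] * (-2.0 * dy)
    np.add.at(gx, aj, cx)
    np.add.at(gy, aj, cy)
    return value, np.vstack([gx, gy]).ravel()


def local_refine(problem: RefineProblem,
                 initial: np.ndarray) -> tuple[np.ndarray, dict]:
    """Quasi-Newton minimization from the polynomial-stage initialization.

    Returns refined (2|A|, 3) coordinates and a diagnostics dict.  The
    result never has a larger objective than the starting point; if the
    line search fails immediately the initial point is returned with
    ``warning`` set.
    """
    na = problem.n_ambiguous
    z0 = np.asarray(initial, dtype=float).reshape(2 * na, 3)
    f0, g0 = objective_and_gradient(problem, z0)

    def fg(flat):
        try:
            return objective_and_gradient(problem, flat.reshape(2 * na, 3))
        except ValueError:
            # singular configuration probed by the line search: reject step
            return 1e30 * (1.0 + f0), np.zeros(flat.shape)

    res = minimize(fg, z0.ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": problem.max_iter,
                            "gtol": problem.grad_tol, "ftol": 1e-16})
    info = {
        "objective_before": f0,
        "objective_after": float(res.fun),
        "converged": bool(res.success),
        "iterations": int(res.nit),
        "warning": None,
    }
    if not np.isfinite(res.fun) or res.fun > f0:
        info["objective_after"] = f0
        info["warning"] = "line search failed at the initial point"
        return z0, info
    return res.x.reshape(2 * na, 3), info
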
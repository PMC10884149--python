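"""Distance geometry: classical MDS, the weighted Gram-cone estimator for
unambiguous beads, Procrustes/RMSD evaluation, and the bipartite index.

Unambiguous bead positions are recovered from their pairwise counts by the
weighted least-squares distance-geometry objective

    min_Z  sum_{c_ij != 0} sqrt(c_ij) (1/c_ij - ||z_i - z_j||^2)^2
         + lambda * sum_{c_ij = 0} ||z_i - z_j||^2,         lambda = 0.01,

(with alpha = -2, 1/c is the model squared distance).  The objective is
attacked through its convex surrogate over the centered positive-semidefinite
Gram matrix G (squared distances are affine in G), solved by projected
gradient descent on the PSD cone, followed by rank-3 spectral extraction and
a quasi-Newton polish of the coordinate objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .model import ContactData, LociPartition, Structure3D

__all__ = [
    "GramEmbedding",
    "AlignmentResult",
    "gram_from_distances",
    "embed_rank3",
    "classical_mds",
    "sdp_estimate_unambiguous",
    "procrustes_rmsd",
    "bipartite_index",
]


@dataclass
class GramEmbedding:
    """Squared-distance matrix with its centering and spectral data."""

    D: np.ndarray
    J: np.ndarray
    Gtilde: np.ndarray
    eigenvalues: np.ndarray | None = None
    Zhat: np.ndarray | None = None


@dataclass
class AlignmentResult:
    """Optimal similarity transform ``z -> s R z + b`` and the residual RMSD."""

    R: np.ndarray
    s: float
    b: np.ndarray
    rmsd: float


def gram_from_distances(D: np.ndarray) -> GramEmbedding:
    """Centered Gram matrix from squared distances: Gtilde = -1/2 J D J."""
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T):
        raise ValueError("D must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("D must have zero diagonal")
    m = D.shape[0]
    J = np.eye(m) - np.ones((m, m)) / m
    Gtilde = -0.5 * (J @ D @ J)
    Gtilde = 0.5 * (Gtilde + Gtilde.T)
    return GramEmbedding(D=D, J=J, Gtilde=Gtilde)


def embed_rank3(Gtilde: np.ndarray) -> np.ndarray:
    """Rank-3 spectral embedding Q Lambda_3^{1/2}.

    Eigenvalues are sorted descending; negative values among the top three
    (present when the input distances are noisy) are clamped to zero before
    the square root.
    """
    Gtilde = np.asarray(Gtilde, dtype=float)
    if not np.allclose(Gtilde, Gtilde.T):
        raise ValueError("Gtilde must be symmetric")
    vals, vecs = np.linalg.eigh(Gtilde)
    order = np.argsort(vals)[::-1]
    top = order[:3]
    lam = np.clip(vals[top], 0.0, None)
    return vecs[:, top] * np.sqrt(lam)[None, :]


def classical_mds(D: np.ndarray) -> GramEmbedding:
    """Full cMDS: distances -> centered Gram -> rank-3 coordinates."""
    emb = gram_from_distances(D)
    vals = np.linalg.eigvalsh(emb.Gtilde)[::-1]
    emb.eigenvalues = vals
    emb.Zhat = embed_rank3(emb.Gtilde)
    return emb


def _pair_terms(contacts: ContactData, partition: LociPartition):
    """Upper-triangle observed / zero-count pair structure on the U beads."""
    n = contacts.n
    beads = np.concatenate([partition.U, partition.U + n])
    C = contacts.cU[np.ix_(beads, beads)]
    M = contacts.mU[np.ix_(beads, beads)]
    iu, ju = np.triu_indices(len(beads), 1)
    avail = M[iu, ju]
    obs = avail & (C[iu, ju] > 0)
    zer = avail & (C[iu, ju] == 0)
    return beads, C, iu, ju, obs, zer


def _coordinate_objective(C, iu, ju, obs, zer, lam):
    """Eq-style weighted objective and analytic gradient in coordinates."""
    sq = np.sqrt(C[iu[obs], ju[obs]])
    target = 1.0 / C[iu[obs], ju[obs]]

    def fg(zflat, m):
        Z = zflat.reshape(m, 3)
        diff_o = Z[iu[obs]] - Z[ju[obs]]
        d2_o = np.einsum("ij,ij->i", diff_o, diff_o)
        res = target - d2_o
        val = float(np.sum(sq * res**2))
        grad = np.zeros_like(Z)
        # d res / d z_i = -2 (z_i - z_j)
        coef = (2.0 * sq * res)[:, None] * (-2.0 * diff_o)
        np.add.at(grad, iu[obs], coef)
        np.add.at(grad, ju[obs], -coef)
        if zer.any():
            diff_z = Z[iu[zer]] - Z[ju[zer]]
            val += lam * float(np.einsum("ij,ij->", diff_z, diff_z))
            np.add.at(grad, iu[zer], 2.0 * lam * diff_z)
            np.add.at(grad, ju[zer], -2.0 * lam * diff_z)
        return val, grad.ravel()

    return fg


def _project_centered_psd(G: np.ndarray) -> np.ndarray:
    m = G.shape[0]
    J = np.eye(m) - np.ones((m, m)) / m
    G = J @ (0.5 * (G + G.T)) @ J
    vals, vecs = np.linalg.eigh(G)
    vals = np.clip(vals, 0.0, None)
    return (vecs * vals) @ vecs.T


def sdp_estimate_unambiguous(
    contacts: ContactData,
    partition: LociPartition,
    lam: float = 0.01,
    gram_iters: int = 200,
    polish: bool = True,
) -> np.ndarray:
    """Estimate the 2|U| unambiguous bead coordinates (centered, own frame).

    Returns an (2|U|, 3) array in bead order ``[x_i for i in U] +
    [y_i for i in U]``.  Requires at least four unambiguous loci.
    """
    if len(partition.U) < 4:
        raise ValueError("need at least 4 unambiguous loci for a stable embedding")
    beads, C, iu, ju, obs, zer = _pair_terms(contacts, partition)
    m = len(beads)
    if not obs.any():
        raise ValueError("no observed unambiguous counts")

    # -- initialization: cMDS on the model squared distances 1/c
    D0 = np.zeros((m, m))
    d2_obs = 1.0 / C[iu[obs], ju[obs]]
    far = float(d2_obs.max())
    fill = np.full(len(iu), far)  # zero-count and unavailable pairs start far out
    fill[obs] = d2_obs
    D0[iu, ju] = fill
    D0 = D0 + D0.T
    G = _project_centered_psd(gram_from_distances(D0).Gtilde)

    # -- projected gradient on the convex Gram-matrix surrogate
    w_obs = np.sqrt(C[iu[obs], ju[obs]])
    t_obs = d2_obs

    def gram_loss_grad(G):
        d2 = np.diag(G)[iu] + np.diag(G)[ju] - 2.0 * G[iu, ju]
        res = t_obs - d2[obs]
        val = float(np.sum(w_obs * res**2)) + lam * float(np.sum(d2[zer]))
        w = np.zeros(len(iu))
        w[obs] = -2.0 * w_obs * res  # d loss / d d2
        w[zer] = lam
        W = np.zeros((m, m))
        W[iu, ju] = w
        W = W + W.T
        grad = np.diag(W.sum(axis=1)) - W  # graph Laplacian of the pair weights
        return val, grad

    val, grad = gram_loss_grad(G)
    step = 1.0 / (np.abs(grad).sum() + 1.0)
    for _ in range(gram_iters):
        cand = _project_centered_psd(G - step * grad)
        cand_val, cand_grad = gram_loss_grad(cand)
        if cand_val <= val:
            if val - cand_val < 1e-10 * (1.0 + abs(val)):
                G, val, grad = cand, cand_val, cand_grad
                break
            G, val, grad = cand, cand_val, cand_grad
            step *= 1.3
        else:
            step *= 0.5
            if step < 1e-16:
                break

    Z0 = embed_rank3(G)

    if polish:
        fg = _coordinate_objective(C, iu, ju, obs, zer, lam)
        res = minimize(
            lambda z: fg(z, m), Z0.ravel(), jac=True, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
        )
        if res.fun <= fg(Z0.ravel(), m)[0]:
            Z0 = res.x.reshape(m, 3)
    return Z0 - Z0.mean(axis=0)


def procrustes_rmsd(
    estimate: Structure3D,
    truth: Structure3D,
    allow_relabel: bool = False,
) -> AlignmentResult:
    """Minimal RMSD between estimate and truth over O(3) rotations (with
    reflections), positive scaling, and translation.

    The 2n beads are stacked pairing x with x* and y with y* (Schoenemann's
    extended orthogonal Procrustes problem, solved in closed form via the
    SVD of the cross covariance).  With ``allow_relabel`` the global homolog
    relabeling (x, y) <-> (y, x) is also minimized over.
    """
    if estimate.n != truth.n:
        raise ValueError("structures must have the same number of loci")

    def solve(E, T):
        mu_e, mu_t = E.mean(axis=0), T.mean(axis=0)
        Ec, Tc = E - mu_e, T - mu_t
        norm_t = float(np.einsum("ij,ij->", Tc, Tc))
        norm_e = float(np.einsum("ij,ij->", Ec, Ec))
        if norm_t <= 0:
            raise ValueError("degenerate truth: all points coincide")
        if norm_e <= 0:
            raise ValueError("degenerate estimate: all points coincide")
        U, S, Vt = np.linalg.svd(Ec.T @ Tc)
        R = (U @ Vt).T  # maps estimate frame onto truth frame
        tr = float(S.sum())
        if tr <= 0:
            raise ValueError("estimate carries no signal for alignment")
        s = tr / norm_e
        b = mu_t - s * (R @ mu_e)
        resid = s * E @ R.T + b - T  # explicit residual avoids cancellation
        rmsd = float(np.sqrt(np.einsum("ij,ij->", resid, resid) / E.shape[0]))
        return AlignmentResult(R=R, s=s, b=b, rmsd=rmsd)

    best = solve(estimate.z, truth.z)
    if allow_relabel:
        swapped = np.vstack([estimate.y, estimate.x])
        alt = solve(swapped, truth.z)
        if alt.rmsd < best.rmsd:
            best = alt
    return best


def bipartite_index(coords: np.ndarray, h: int) -> float:
    """Bipartite index BI(h) of one homolog split after bead ``h``.

    Reconstructed contacts are 1/||z_i - z_j||^2; BI is the ratio of the
    mean intra-superdomain contact (both blocks, self pairs i = j excluded
    since the power law diverges there) to the mean inter-superdomain
    contact.  ``h`` is 1-based: the first superdomain is beads 1..h.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if not 1 <= h <= n - 1:
        raise ValueError("h must satisfy 1 <= h <= n-1")
    diff = coords[:, None, :] - coords[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    off = ~np.eye(n, dtype=bool)
    if (d2[off] <= 0).any():
        raise ValueError("coincident beads make a contact term singular")
    w = np.zeros_like(d2)
    w[off] = 1.0 / d2[off]

    first = slice(0, h)
    second = slice(h, n)

    def intra_mean(sl, k):
        if k < 2:
            return 0.0
        block = w[sl, sl]
        return float(block.sum() / (k * (k - 1)))  # ordered pairs, i != j

    num = intra_mean(first, h) + intra_mean(second, n - h)
    inter = float(w[first, second].sum())
    den = 2.0 * inter / (h * (n - h))
    return num / den
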
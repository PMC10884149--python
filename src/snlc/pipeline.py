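"""End-to-end orchestration of the four reconstruction stages.

``reconstruct`` runs, in order: distance-geometry estimation of the
unambiguous beads, per-locus polynomial consensus estimation of the
ambiguous pairs, joint local refinement, and exact swap disambiguation.
``filter_loci`` prepares real partially phased datasets (where a locus may
participate in all three count classes) for the pure-partition setting the
method assumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .disambiguate import SignAssignment, apply_signs, optimal_signs
from .euclid import sdp_estimate_unambiguous
from .model import ContactData, LociPartition, Structure3D, _availability_masks
from .polysolve import estimate_ambiguous_pair
from .refine import RefineProblem, local_refine

__all__ = ["ReconstructionConfig", "ReconstructionResult", "reconstruct",
           "filter_loci", "coverage_ratio_report"]


@dataclass
class ReconstructionConfig:
    lam: float = 0.01  # zero-count penalty weight of the distance-geometry stage
    N: int = 5  # consensus draws per ambiguous locus
    pool: int = 20  # anchor pool: top beads by partially ambiguous count
    max_attempts: int = 100  # anchor redraws before the fallback estimate
    real_tol: float = 0.15  # imaginary-part tolerance for approximate realness
    seed: int = 0
    phase1_seed: int = 2023
    refine: bool = True
    disambiguate: bool = True
    rescale: bool = False  # normalize counts to unit median distance first


@dataclass
class ReconstructionResult:
    structure: Structure3D  # final estimate, in its own (centered) frame
    partition: LociPartition
    flags: dict[int, str]  # per ambiguous locus: "solved" / "fallback"
    signs: SignAssignment | None
    diagnostics: dict
    config: ReconstructionConfig


def rescale_contacts(contacts: ContactData) -> tuple[ContactData, float]:
    """Normalize counts so the median nonzero unambiguous distance is 1.

    With alpha = -2 a coordinate scale s multiplies every count by s^-2,
    so multiplying the counts by the squared median model distance brings
    the structure to unit scale — where the absolute imaginary-part
    tolerance of the polynomial stage is calibrated.  Returns the scaled
    counts and the median distance (the factor to re-apply to coordinates).
    """
    vals = contacts.cU[contacts.mU & (contacts.cU > 0)]
    if vals.size == 0:
        raise ValueError("no nonzero unambiguous counts to estimate scale from")
    d_med = float(np.median(1.0 / np.sqrt(vals)))
    out = contacts.copy()
    out.cU = out.cU * d_med**2
    out.cP = out.cP * d_med**2
    out.cA = out.cA * d_med**2
    return out, d_med


def reconstruct(contacts: ContactData, partition: LociPartition,
                config: ReconstructionConfig | None = None) -> ReconstructionResult:
    """Run the full reconstruction.  Requires alpha = -2 and |U| >= 6
    whenever there are ambiguous loci (|U| >= 4 otherwise)."""
    config = config or ReconstructionConfig()
    if Fraction(contacts.alpha) != Fraction(-2):
        raise ValueError("the reconstruction method requires alpha = -2")
    if config.rescale:
        contacts, scale_back = rescale_contacts(contacts)
        inner = ReconstructionConfig(**{**config.__dict__, "rescale": False})
        result = reconstruct(contacts, partition, inner)
        result.structure = Structure3D(result.structure.x * scale_back,
                                       result.structure.y * scale_back)
        result.diagnostics["rescale_factor"] = scale_back
        result.config = config
        return result
    n = contacts.n
    has_ambiguous = len(partition.A) > 0
    if has_ambiguous and len(partition.U) < 6:
        raise ValueError("need at least six unambiguous loci")

    diagnostics: dict = {"seed": config.seed}
    ss = np.random.SeedSequence(config.seed)
    locus_seeds = {int(j): int(s.generate_state(1)[0] % (2**31))
                   for j, s in zip(partition.A, ss.spawn(max(len(partition.A), 1)))}

    # stage 1: unambiguous beads
    Zu = sdp_estimate_unambiguous(contacts, partition, lam=config.lam)
    nu = len(partition.U)

    x = np.zeros((n, 3))
    y = np.zeros((n, 3))
    x[partition.U] = Zu[:nu]
    y[partition.U] = Zu[nu:]

    flags: dict[int, str] = {}
    signs = None
    if has_ambiguous:
        # stage 2: per-locus polynomial consensus
        for j in partition.A:
            xj, yj, flag = estimate_ambiguous_pair(
                int(j), Zu, contacts, partition,
                N=config.N, pool=config.pool, max_attempts=config.max_attempts,
                tol=config.real_tol, seed=locus_seeds[int(j)],
                phase1_seed=config.phase1_seed,
            )
            x[j], y[j] = xj, yj
            flags[int(j)] = flag
        diagnostics["fallback_loci"] = [j for j, f in flags.items() if f == "fallback"]

        # stage 3: joint refinement against all partially ambiguous counts
        if config.refine:
            problem = RefineProblem(Zu, contacts, partition)
            init = np.vstack([x[partition.A], y[partition.A]])
            refined, info = local_refine(problem, init)
            na = len(partition.A)
            x[partition.A] = refined[:na]
            y[partition.A] = refined[na:]
            diagnostics["refine"] = info
            for j in partition.A:
                if flags[int(j)] == "solved":
                    flags[int(j)] = "refined"

        # stage 4: exact swap disambiguation
        structure = Structure3D(x, y)
        if config.disambiguate:
            signs = optimal_signs(x, y, partition)
            structure = apply_signs(structure, signs)
            diagnostics["sign_vector"] = signs.s.tolist()
            diagnostics["sign_objective"] = signs.objective
    else:
        structure = Structure3D(x, y)

    return ReconstructionResult(structure=structure, partition=partition,
                                flags=flags, signs=signs,
                                diagnostics=diagnostics, config=config)


# ---------------------------------------------------------------------------
# real-data preparation

def _locus_totals(raw: ContactData):
    """Per-locus phased and unphased contact totals.

    A contact is phased *for locus i* if i's bead was distinguished in it:
    its cU rows and cP rows (phased side).  It is unphased for i if i is
    the unresolved side: cP columns and cA rows.
    """
    n = raw.n
    phased = raw.cU[:n].sum(axis=1) + raw.cU[n:].sum(axis=1) \
        + raw.cP[:n].sum(axis=1) + raw.cP[n:].sum(axis=1)
    unphased = raw.cP.sum(axis=0) + raw.cA.sum(axis=1)
    return phased, unphased


def coverage_ratio_report(raw: ContactData) -> dict:
    """Diagnostic for choosing the low-coverage cutoff.

    Sorts loci by total contact count and reports the ratios between
    consecutive totals; a pronounced peak in the ratios marks the boundary
    between dropout loci and well-covered ones, and its position is a
    candidate for ``filter_loci``'s ``drop_lowest``.
    """
    phased, unphased = _locus_totals(raw)
    total = phased + unphased
    order = np.argsort(total, kind="stable")
    sorted_totals = total[order]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.divide(sorted_totals[1:], sorted_totals[:-1],
                           out=np.full(len(sorted_totals) - 1, np.inf),
                           where=sorted_totals[:-1] > 0)
    finite = np.where(np.isfinite(ratios))[0]
    peak = int(finite[np.argmax(ratios[finite])]) + 1 if len(finite) else 0
    return {
        "order": order,
        "sorted_totals": sorted_totals,
        "consecutive_ratios": ratios,
        "suggested_drop_lowest": peak,
    }


def filter_loci(raw: ContactData, drop_lowest: int = 47,
                phased_fraction_threshold: float = 0.40,
                reassign: bool = True):
    """Filter low-coverage loci and force a pure U/A partition.

    Loci are sorted by total contact count and the lowest ``drop_lowest``
    are removed; each remaining locus is labelled ambiguous iff less than
    ``phased_fraction_threshold`` of its total count comes from contacts
    in which its beads were distinguished.  With ``reassign``, counts are
    then redistributed so every retained locus is wholly unambiguous or
    wholly ambiguous: counts phased for a now-ambiguous locus are summed
    into its ambiguous bins, and counts unphased for a now-unambiguous
    locus are split over its beads proportionally to its observed phased
    profile (evenly when no profile exists).

    Returns ``(kept_loci, partition, contacts)`` where ``kept_loci`` maps
    the new 0-based loci to the original indices.
    """
    n = raw.n
    if drop_lowest >= n:
        raise ValueError("drop_lowest must be smaller than the loci count")
    phased, unphased = _locus_totals(raw)
    total = phased + unphased
    order = np.argsort(total, kind="stable")
    kept = np.sort(order[drop_lowest:])
    m = len(kept)

    frac = np.divide(phased, total, out=np.zeros(n), where=total > 0)
    ambiguous_new = [k for k, i in enumerate(kept)
                     if frac[i] < phased_fraction_threshold]
    U_new = np.setdiff1d(np.arange(m), ambiguous_new)
    partition = LociPartition(m, U_new, np.asarray(ambiguous_new, dtype=int))

    cU = np.zeros((2 * m, 2 * m))
    cP = np.zeros((2 * m, m))
    cA = np.zeros((m, m))
    inA = np.zeros(m, dtype=bool)
    inA[partition.A] = True

    def old_beads(i):
        return kept[i], kept[i] + n

    for a in range(m):
        oa, oa2 = old_beads(a)
        for b in range(a + 1, m):
            ob, ob2 = old_beads(b)
            blockU = raw.cU[np.ix_([oa, oa2], [ob, ob2])]
            pa = raw.cP[[oa, oa2], kept[b]]  # a phased, b unphased
            pb = raw.cP[[ob, ob2], kept[a]]  # b phased, a unphased
            amb = raw.cA[kept[a], kept[b]]
            if not reassign:
                blockU = blockU.copy()
                pa = pa.copy()
                pb = pb.copy()
            if inA[a] and inA[b]:
                cA[a, b] = cA[b, a] = blockU.sum() + pa.sum() + pb.sum() + amb
            elif not inA[a] and inA[b]:
                # target: cP rows of a's beads against locus b
                base = blockU.sum(axis=1) + pa  # phased profile of a towards b
                wts = base / base.sum() if base.sum() > 0 else np.array([0.5, 0.5])
                extra = pb.sum() + amb
                cP[a, b] = base[0] + wts[0] * extra
                cP[a + m, b] = base[1] + wts[1] * extra
            elif inA[a] and not inA[b]:
                base = blockU.sum(axis=0) + pb
                wts = base / base.sum() if base.sum() > 0 else np.array([0.5, 0.5])
                extra = pa.sum() + amb
                cP[b, a] = base[0] + wts[0] * extra
                cP[b + m, a] = base[1] + wts[1] * extra
            else:
                # both unambiguous: spread unphased counts over the four bead
                # pairs proportionally to the phased profile
                extra = pa.sum() + pb.sum() + amb
                wts = (blockU / blockU.sum() if blockU.sum() > 0
                       else np.full((2, 2), 0.25))
                block = blockU + wts * extra
                for u, gi in enumerate((a, a + m)):
                    for v, gj in enumerate((b, b + m)):
                        cU[gi, gj] = cU[gj, gi] = block[u, v]

    mU, mP, mA = _availability_masks(partition)
    contacts = ContactData(m, cU * mU, cP * mP, cA * mA, mU, mP, mA,
                           alpha=raw.alpha, gamma=raw.gamma)
    return kept, partition, contacts
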
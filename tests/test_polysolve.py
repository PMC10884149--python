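"""Six-anchor polynomial systems: root counts, homotopy tracking, consensus."""

import numpy as np
import pytest

from snlc.model import LociPartition, contacts_from_structure
from snlc.polysolve import (AnchorSystem, approximately_real, consensus_estimate,
                            estimate_ambiguous_pair, solve_phase2, swap_xy)
from snlc.simulate import SimulationConfig, make_dataset


def planted_system(seed, noise=0.0, separation=3.0):
    """Real anchors and counts from a planted (x*, y*); returns system, truth."""
    rng = np.random.default_rng(seed)
    anchors = rng.standard_normal((6, 3))
    xs = rng.standard_normal(3)
    ys = rng.standard_normal(3) + np.array([separation, 0.0, 0.0])
    qx = ((xs - anchors) ** 2).sum(axis=1)
    qy = ((ys - anchors) ** 2).sum(axis=1)
    c = (1.0 / qx + 1.0 / qy)
    if noise:
        c = c * (1.0 + rng.uniform(-noise, noise, 6))
    return AnchorSystem(anchors, c), np.concatenate([xs, ys])


class TestPhase1:
    def test_generic_count_and_orbits(self, phase1_start):
        assert len(phase1_start.solutions) == 80
        assert phase1_start.orbit_count == 40
        assert phase1_start.stabilized

    def test_residual_certificates(self, phase1_start):
        assert phase1_start.residuals.max() < 1e-8

    def test_swap_closure(self, phase1_start):
        sols = phase1_start.solutions
        for z in sols:
            d = np.abs(sols - swap_xy(z)[None]).max(axis=1)
            assert d.min() < 1e-6

    def test_count_invariant_across_seeds(self):
        # independent monodromy run from a different seed
        from snlc.polysolve import solve_phase1

        other = solve_phase1(99)
        assert len(other.solutions) == 80
        assert other.orbit_count == 40

    def test_bound_chain(self, phase1_start):
        from snlc.identifiability import BEZOUT_BOUND

        assert len(phase1_start.solutions) <= 1280 <= BEZOUT_BOUND


class TestPhase1Serialization:
    def test_round_trip(self, tmp_path, phase1_start):
        from snlc.polysolve import load_phase1, save_phase1

        path = tmp_path / "phase1.json"
        save_phase1(phase1_start, path, seed=2023)
        back, seed = load_phase1(path)
        assert seed == 2023
        assert np.allclose(back.solutions, phase1_start.solutions)
        assert np.allclose(back.anchors, phase1_start.anchors)
        assert np.allclose(back.counts, phase1_start.counts)
        # the reloaded start is usable for a phase-2 continuation
        system, z = planted_system(31)
        out = solve_phase2(back, system, seed=0)
        d = min(np.abs(out.solutions - z[None]).max(axis=1).min(),
                np.abs(out.solutions - swap_xy(z)[None]).max(axis=1).min())
        assert d < 1e-6


class TestPhase2:
    def test_zero_length_homotopy(self, phase1_start):
        target = AnchorSystem(phase1_start.anchors, phase1_start.counts)
        out = solve_phase2(phase1_start, target)
        assert len(out.solutions) == len(phase1_start.solutions)
        d = np.abs(out.solutions[:, None] - phase1_start.solutions[None]).max(-1)
        assert d.min(axis=1).max() < 1e-8

    def test_planted_noiseless_recovery(self, phase1_start):
        system, z = planted_system(21)
        out = solve_phase2(phase1_start, system, seed=0)
        d = min(np.abs(out.solutions - z[None]).max(axis=1).min(),
                np.abs(out.solutions - swap_xy(z)[None]).max(axis=1).min())
        assert d < 1e-6

    def test_paths_tracked_is_orbit_count(self, phase1_start):
        system, _ = planted_system(22)
        out = solve_phase2(phase1_start, system, seed=0)
        assert out.n_paths_tracked == 40

    def test_target_residuals(self, phase1_start):
        system, _ = planted_system(23, noise=0.2)
        out = solve_phase2(phase1_start, system, seed=1)
        assert out.residuals.max() < 1e-8
        # solution set is swap closed
        for z in out.solutions:
            d = np.abs(out.solutions - swap_xy(z)[None]).max(axis=1)
            assert d.min() < 1e-6


class TestApproximatelyReal:
    def test_exactly_real_retained(self):
        sols = np.array([[1.0, 2, 3, 4, 5, 6]], dtype=complex)
        assert len(approximately_real(sols)) == 1

    def test_threshold(self):
        z = np.ones((1, 6), dtype=complex)
        z[0, 2] += 0.2j
        assert len(approximately_real(z, tol=0.15)) == 0
        assert len(approximately_real(z, tol=0.25)) == 1

    def test_default_tolerance(self):
        import inspect

        from snlc.polysolve import approximately_real as ar

        assert inspect.signature(ar).parameters["tol"].default == 0.15


class TestConsensus:
    def test_identical_candidates(self):
        v = np.arange(6.0)
        out = consensus_estimate([v[None]] * 5)
        assert np.allclose(out, v) or np.allclose(out, swap_xy(v))

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(6)
        q = v + 8.0
        r = v - 11.0
        sets = [np.vstack([v, q]), np.vstack([swap_xy(v), r])]
        out = consensus_estimate(sets)
        # brute-force oracle: independent re-implementation over the product
        from itertools import product

        aug = [np.vstack([s, swap_xy(s)]) for s in sets]
        best, best_val = None, np.inf
        for combo in product(*aug):
            W = np.array(combo)
            mean = W.mean(axis=0)
            val = np.linalg.norm(W - mean, axis=1).sum()
            if val < best_val:
                best_val, best = val, mean
        assert np.allclose(out, best)
        assert np.allclose(np.minimum(np.abs(out - v), np.abs(out - swap_xy(v))), 0,
                           atol=1e-12)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            consensus_estimate([np.ones((1, 6)), np.zeros((0, 6))])

    def test_single_set_rejected(self):
        with pytest.raises(ValueError):
            consensus_estimate([np.ones((1, 6))])


class TestEstimateAmbiguousPair:
    def test_noiseless_recovery_up_to_swap(self, phase1_start):
        truth, part, contacts = make_dataset(
            SimulationConfig(n=14, ambiguous_fraction=0.4, seed=17))
        nu = len(part.U)
        coords = np.vstack([truth.x[part.U], truth.y[part.U]])
        for j in part.A[:3]:
            x, y, flag = estimate_ambiguous_pair(int(j), coords, contacts, part,
                                                 seed=5)
            assert flag == "solved"
            z = np.concatenate([truth.x[j], truth.y[j]])
            est = np.concatenate([x, y])
            d = min(np.abs(est - z).max(), np.abs(est - swap_xy(z)).max())
            assert d < 1e-4

    def test_too_few_unambiguous_error(self):
        truth, part, contacts = make_dataset(
            SimulationConfig(n=10, ambiguous_fraction=0.5, seed=2))
        bad = LociPartition(10, U=part.U[:5].tolist(),
                            A=sorted(set(range(10)) - set(part.U[:5].tolist())))
        coords = np.zeros((10, 3))
        with pytest.raises(ValueError, match="six"):
            estimate_ambiguous_pair(int(bad.A[0]), coords, contacts, bad, seed=0)

    def test_defaults_match_protocol(self):
        import inspect

        sig = inspect.signature(estimate_ambiguous_pair)
        assert sig.parameters["N"].default == 5
        assert sig.parameters["pool"].default == 20
        assert sig.parameters["max_attempts"].default == 100
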
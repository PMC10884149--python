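"""Distance geometry, Procrustes evaluation, and the bipartite index."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from snlc.euclid import (bipartite_index, classical_mds, embed_rank3,
                         gram_from_distances, procrustes_rmsd,
                         sdp_estimate_unambiguous)
from snlc.model import LociPartition, Structure3D, add_noise, contacts_from_structure
from snlc.simulate import SimulationConfig, brownian_pair

from conftest import random_structure


def squared_distances(Z):
    diff = Z[:, None, :] - Z[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


class TestGramFromDistances:
    def test_zero_distances(self):
        emb = gram_from_distances(np.zeros((4, 4)))
        assert np.allclose(emb.Gtilde, 0.0)

    def test_two_points_hand_computed(self):
        emb = gram_from_distances(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.allclose(emb.Gtilde, [[0.25, -0.25], [-0.25, 0.25]])

    def test_matches_centered_gram_product(self):
        rng = np.random.default_rng(0)
        Z = rng.standard_normal((12, 3))
        emb = gram_from_distances(squared_distances(Z))
        Zc = Z - Z.mean(axis=0)
        assert np.allclose(emb.Gtilde, Zc @ Zc.T, atol=1e-10)

    def test_centering(self):
        rng = np.random.default_rng(1)
        Z = rng.standard_normal((9, 3))
        emb = gram_from_distances(squared_distances(Z))
        assert np.allclose(emb.Gtilde @ np.ones(9), 0.0, atol=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gram_from_distances(np.arange(9.0).reshape(3, 3))
        with pytest.raises(ValueError):
            gram_from_distances(np.eye(3))


class TestEmbedRank3:
    def test_round_trip_distances(self):
        rng = np.random.default_rng(2)
        Z = rng.standard_normal((15, 3))
        D = squared_distances(Z)
        Zhat = embed_rank3(gram_from_distances(D).Gtilde)
        assert np.allclose(squared_distances(Zhat), D, atol=1e-8)

    def test_collinear_points_third_coordinate_zero(self):
        t = np.linspace(0, 1, 8)
        Z = np.column_stack([t, 2 * t, -t])
        Zhat = embed_rank3(gram_from_distances(squared_distances(Z)).Gtilde)
        # spectral truncation of a rank-1 Gram: higher coordinates vanish up
        # to sqrt(machine-epsilon) noise of the zero eigenvalues
        assert np.allclose(Zhat[:, 1:], 0.0, atol=1e-6)

    def test_noisy_input_still_finite(self):
        rng = np.random.default_rng(3)
        Z = rng.standard_normal((10, 3))
        D = squared_distances(Z)
        noisy = D * (1 + 0.1 * rng.uniform(-1, 1, D.shape))
        noisy = 0.5 * (noisy + noisy.T)
        np.fill_diagonal(noisy, 0.0)
        Zhat = embed_rank3(gram_from_distances(noisy).Gtilde)
        assert Zhat.shape == (10, 3) and np.isfinite(Zhat).all()

    def test_exactly_three_significant_eigenvalues(self):
        rng = np.random.default_rng(4)
        Z = rng.standard_normal((20, 3))
        emb = classical_mds(squared_distances(Z))
        lam = emb.eigenvalues
        assert np.sum(np.abs(lam) > 1e-8 * lam[0]) == 3


class TestProcrustes:
    def test_identity(self):
        rng = np.random.default_rng(5)
        s = random_structure(rng, 8)
        res = procrustes_rmsd(s, s)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.R, np.eye(3), atol=1e-8)
        assert res.s == pytest.approx(1.0)
        assert np.allclose(res.b, 0.0, atol=1e-8)

    def test_similarity_transform_invariance(self):
        rng = np.random.default_rng(6)
        s = random_structure(rng, 10)
        R0 = Rotation.random(random_state=7).as_matrix()
        b0 = rng.standard_normal(3)
        est = Structure3D(2.0 * s.x @ R0.T + b0, 2.0 * s.y @ R0.T + b0)
        assert procrustes_rmsd(est, s).rmsd <= 1e-10

    def test_reflection_allowed(self):
        rng = np.random.default_rng(8)
        s = random_structure(rng, 10)
        F = np.diag([1.0, 1.0, -1.0])
        est = Structure3D(s.x @ F, s.y @ F)
        assert procrustes_rmsd(est, s).rmsd <= 1e-10

    def test_matches_numerical_minimization(self):
        # independent oracle: direct minimization over (rotvec, log s, b)
        rng = np.random.default_rng(9)
        truth = random_structure(rng, 6)
        est = Structure3D(truth.x + 0.3 * rng.standard_normal((6, 3)),
                          truth.y + 0.3 * rng.standard_normal((6, 3)))
        closed = procrustes_rmsd(est, truth).rmsd

        E, T = est.z, truth.z

        def objective(p):
            R = Rotation.from_rotvec(p[:3]).as_matrix()
            s = np.exp(p[3])
            b = p[4:]
            diff = s * E @ R.T + b - T
            return np.sqrt((diff**2).sum() / len(E))

        best = np.inf
        for k in range(12):
            p0 = np.concatenate([rng.uniform(-np.pi, np.pi, 3), [0.0],
                                 rng.standard_normal(3)])
            r = minimize(objective, p0, method="Nelder-Mead",
                         options={"maxiter": 4000, "xatol": 1e-12, "fatol": 1e-14})
            best = min(best, r.fun)
        assert closed == pytest.approx(best, abs=1e-6)

    def test_global_relabel_option(self):
        rng = np.random.default_rng(10)
        s = random_structure(rng, 8)
        swapped = Structure3D(s.y, s.x)
        plain = procrustes_rmsd(swapped, s)
        relabeled = procrustes_rmsd(swapped, s, allow_relabel=True)
        assert relabeled.rmsd <= 1e-10 < plain.rmsd

    def test_degenerate_truth_error(self):
        est = Structure3D(np.random.default_rng(0).standard_normal((3, 3)),
                          np.random.default_rng(1).standard_normal((3, 3)))
        truth = Structure3D(np.ones((3, 3)), np.ones((3, 3)))
        with pytest.raises(ValueError, match="degenerate"):
            procrustes_rmsd(est, truth)


class TestSdpEstimate:
    @pytest.mark.parametrize("seed", range(5))
    def test_noiseless_parameter_recovery(self, seed):
        s = brownian_pair(SimulationConfig(n=10, seed=seed))
        part = LociPartition.all_unambiguous(10)
        contacts = contacts_from_structure(s, part)
        Z = sdp_estimate_unambiguous(contacts, part)
        est = Structure3D(Z[:10], Z[10:])
        assert procrustes_rmsd(est, s).rmsd <= 1e-3

    def test_noisy_beats_random_baseline(self):
        s = brownian_pair(SimulationConfig(n=10, seed=3))
        part = LociPartition.all_unambiguous(10)
        contacts = add_noise(contacts_from_structure(s, part), 0.1, seed=1)
        Z = sdp_estimate_unambiguous(contacts, part)
        est = Structure3D(Z[:10], Z[10:])
        rmsd = procrustes_rmsd(est, s).rmsd
        assert np.isfinite(rmsd)
        rng = np.random.default_rng(0)
        base = random_structure(rng, 10)
        assert rmsd < procrustes_rmsd(base, s).rmsd

    def test_observed_term_weight_is_sqrt_of_count(self):
        # single-term objective with c = 4 and squared distance 1:
        # value must be sqrt(4) * (1/4 - 1)^2
        from snlc.euclid import _coordinate_objective

        C = np.array([[0.0, 4.0], [4.0, 0.0]])
        iu = np.array([0])
        ju = np.array([1])
        obs = np.array([True])
        zer = np.array([False])
        fg = _coordinate_objective(C, iu, ju, obs, zer, lam=0.01)
        Z = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        val, _ = fg(Z.ravel(), 2)
        assert val == pytest.approx(2.0 * (0.25 - 1.0) ** 2, rel=1e-12)

    def test_too_few_loci_error(self):
        s = brownian_pair(SimulationConfig(n=3, seed=0))
        part = LociPartition.all_unambiguous(3)
        contacts = contacts_from_structure(s, part)
        with pytest.raises(ValueError):
            sdp_estimate_unambiguous(contacts, part)


class TestBipartiteIndex:
    def test_two_clusters_peak_at_boundary(self):
        rng = np.random.default_rng(11)
        k = 6
        a = 0.2 * rng.standard_normal((k, 3))
        b = 0.2 * rng.standard_normal((k, 3)) + np.array([50.0, 0, 0])
        coords = np.vstack([a, b])
        values = [bipartite_index(coords, h) for h in range(1, 2 * k)]
        assert int(np.argmax(values)) + 1 == k
        assert values[k - 1] > 100.0

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(12)
        coords = rng.standard_normal((9, 3))
        n = 9
        for h in (1, 3, 5, 8):
            w = lambda i, j: 1.0 / ((coords[i] - coords[j]) ** 2).sum()
            intra1 = sum(w(i, j) for i in range(h) for j in range(h) if i != j)
            intra1 = intra1 / (h * (h - 1)) if h > 1 else 0.0
            m = n - h
            intra2 = sum(w(i, j) for i in range(h, n) for j in range(h, n) if i != j)
            intra2 = intra2 / (m * (m - 1)) if m > 1 else 0.0
            inter = sum(w(i, j) for i in range(h) for j in range(h, n))
            expected = (intra1 + intra2) / (2.0 * inter / (h * m))
            assert bipartite_index(coords, h) == pytest.approx(expected, rel=1e-10)

    def test_h_out_of_range(self):
        coords = np.random.default_rng(0).standard_normal((5, 3))
        with pytest.raises(ValueError):
            bipartite_index(coords, 0)
        with pytest.raises(ValueError):
            bipartite_index(coords, 5)

    def test_coincident_beads_error(self):
        coords = np.zeros((4, 3))
        with pytest.raises(ValueError, match="coincident"):
            bipartite_index(coords, 2)
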
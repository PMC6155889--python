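"""Elastic-model matrices, spectra and derived observables.

The independent oracles here are deliberate: brute-force double loops for
the Kirchhoff matrix, central finite differences of the pair potential
for the Hessian, and the Moore-Penrose pseudo-inverse for GNM
fluctuations.
"""
import numpy as np
import pytest

from nacage import (ENMConfig, NodeModel, cross_correlation, diagonalize,
                    diagonalize_partial, gnm_pseudoinverse_fluctuations,
                    hessian, kirchhoff, square_fluctuations)
from nacage.errors import (DisconnectedNetworkWarning, DuplicateNodeError,
                           InvalidArgumentError, InvalidModeError)


def make_nodes(positions, level=3):
    positions = np.asarray(positions, dtype=float)
    meta = [("A", i + 1, "P", None) for i in range(len(positions))]
    return NodeModel(level=level, positions=positions, node_meta=meta)


class TestKirchhoff:
    def test_two_nodes_in_contact(self):
        nodes = make_nodes([[0, 0, 0], [5, 0, 0]])
        g = kirchhoff(nodes, ENMConfig("GNM", cutoff=10))
        assert np.array_equal(g, [[1, -1], [-1, 1]])

    def test_two_nodes_out_of_contact(self):
        nodes = make_nodes([[0, 0, 0], [12, 0, 0]])
        g = kirchhoff(nodes, ENMConfig("GNM", cutoff=10))
        assert np.array_equal(g, np.zeros((2, 2)))

    def test_matches_brute_force(self, rng):
        pos = rng.uniform(0, 30, (50, 3))
        g = kirchhoff(make_nodes(pos), ENMConfig("GNM", cutoff=10))
        ref = np.zeros((50, 50))
        for i in range(50):
            for j in range(50):
                if i != j and np.linalg.norm(pos[i] - pos[j]) <= 10:
                    ref[i, j] = -1
        np.fill_diagonal(ref, -ref.sum(axis=1))
        assert np.array_equal(g, ref)

    def test_duplicate_nodes_rejected(self):
        nodes = make_nodes([[0, 0, 0], [0, 0, 0], [5, 0, 0]])
        with pytest.raises(DuplicateNodeError):
            kirchhoff(nodes, ENMConfig("GNM", cutoff=10))

    def test_row_sums_exactly_zero(self, cage_nodes_l3):
        g = kirchhoff(cage_nodes_l3, ENMConfig("GNM"))
        assert np.abs(g.sum(axis=1)).max() == 0.0

    def test_contact_count_monotone_in_cutoff(self, helix_nodes):
        counts = []
        for rc in (5.0, 8.0, 12.0, 20.0):
            g = kirchhoff(helix_nodes, ENMConfig("GNM", cutoff=rc))
            counts.append(int(np.trace(g)))
        assert counts == sorted(counts)


def anm_potential(pos0, pos, cutoff, gamma=1.0):
    """V = (gamma/2) sum over native contacts of (|Rij| - |Rij0|)^2."""
    v = 0.0
    n = len(pos0)
    for i in range(n):
        for j in range(i + 1, n):
            d0 = np.linalg.norm(pos0[j] - pos0[i])
            if d0 <= cutoff:
                d = np.linalg.norm(pos[j] - pos[i])
                v += 0.5 * gamma * (d - d0) ** 2
    return v


class TestHessian:
    def test_two_node_super_element(self):
        nodes = make_nodes([[0, 0, 0], [5, 0, 0]])
        h = hessian(nodes, ENMConfig("ANM", cutoff=10))
        assert np.allclose(h[0:3, 3:6], np.diag([-1.0, 0.0, 0.0]))
        assert np.allclose(h[0:3, 0:3], np.diag([1.0, 0.0, 0.0]))

    def test_row_sums_exactly_zero(self, helix_nodes):
        h = hessian(helix_nodes, ENMConfig("ANM"))
        assert np.abs(h.sum(axis=1)).max() < 1e-10

    def test_matches_finite_differences(self, rng):
        pos0 = rng.uniform(0, 15, (12, 3))
        cutoff = 8.0
        h = hessian(make_nodes(pos0), ENMConfig("ANM", cutoff=cutoff))
        x0 = pos0.ravel()
        step = 1e-5
        dim = x0.size
        ref = np.zeros((dim, dim))
        for a in range(dim):
            for b in range(a, dim):
                vpp = vpm = vmp = vmm = None
                for sa, sb, slot in [(1, 1, "pp"), (1, -1, "pm"),
                                     (-1, 1, "mp"), (-1, -1, "mm")]:
                    x = x0.copy()
                    x[a] += sa * step
                    x[b] += sb * step
                    val = anm_potential(pos0, x.reshape(-1, 3), cutoff)
                    if slot == "pp":
                        vpp = val
                    elif slot == "pm":
                        vpm = val
                    elif slot == "mp":
                        vmp = val
                    else:
                        vmm = val
                ref[a, b] = ref[b, a] = (vpp - vpm - vmp + vmm) / (
                    4 * step ** 2)
        assert np.abs(h - ref).max() < 1e-4


class TestDiagonalize:
    def test_two_by_two_closed_form(self):
        modes = diagonalize(np.array([[1.0, -1.0], [-1.0, 1.0]]), "GNM")
        assert modes.n_zero_excluded == 1
        assert modes.eigenvalues == pytest.approx([2.0])

    def test_cage_gnm_single_zero_mode(self, cage_gnm_l3):
        assert cage_gnm_l3.n_zero_excluded == 1

    def test_cage_anm_six_zero_modes(self, cage_anm_l3):
        assert cage_anm_l3.n_zero_excluded == 6

    def test_eigenvectors_orthonormal(self, helix_gnm):
        v = helix_gnm.eigenvectors
        assert np.abs(v.T @ v - np.eye(v.shape[1])).max() < 1e-8

    def test_disconnected_network_warns_with_components(self):
        pos = np.vstack([np.random.default_rng(1).uniform(0, 5, (5, 3)),
                         np.random.default_rng(2).uniform(40, 45, (5, 3))])
        g = kirchhoff(make_nodes(pos), ENMConfig("GNM", cutoff=10))
        with pytest.warns(DisconnectedNetworkWarning) as rec:
            diagonalize(g, "GNM")
        assert rec[0].message.n_components == 2

    def test_sparse_solver_matches_dense(self, helix_nodes):
        cfg = ENMConfig("GNM")
        g = kirchhoff(helix_nodes, cfg)
        dense = diagonalize(g, "GNM", cfg)
        part = diagonalize_partial(g, "GNM", n_modes=20, config=cfg)
        assert np.allclose(part.eigenvalues[:20], dense.eigenvalues[:20],
                           atol=1e-6)
        for k in range(1, 21):
            dot = abs(np.dot(part.mode(k), dense.mode(k)))
            assert dot == pytest.approx(1.0, abs=1e-6)


class TestFluctuations:
    def test_gnm_equals_pseudoinverse(self, helix_nodes):
        cfg = ENMConfig("GNM")
        g = kirchhoff(helix_nodes, cfg)
        modes = diagonalize(g, "GNM", cfg)
        via_modes = square_fluctuations(modes).values
        via_pinv = gnm_pseudoinverse_fluctuations(g)
        assert np.abs(via_modes - via_pinv).max() < 1e-8

    def test_single_mode_sums_to_inverse_eigenvalue(self, helix_gnm):
        prof = square_fluctuations(helix_gnm, [1])
        assert prof.values.sum() == pytest.approx(
            1.0 / helix_gnm.eigenvalues[0])

    def test_gamma_scaling(self, helix_nodes):
        base = diagonalize(kirchhoff(helix_nodes, ENMConfig("GNM")), "GNM")
        scaled_cfg = ENMConfig("GNM", gamma=4.0)
        scaled = diagonalize(kirchhoff(helix_nodes, scaled_cfg), "GNM",
                             scaled_cfg)
        f0 = square_fluctuations(base).values
        f1 = square_fluctuations(scaled).values
        assert np.allclose(f1, f0 / 4.0, rtol=1e-10)
        c0 = cross_correlation(base, 10).values
        c1 = cross_correlation(scaled, 10).values
        assert np.abs(c0 - c1).max() < 1e-8

    def test_rigid_rotation_invariance(self, helix_nodes, rng):
        from scipy.spatial.transform import Rotation
        rot = Rotation.random(random_state=rng)
        rotated = make_nodes(rot.apply(helix_nodes.positions))
        rotated.level = helix_nodes.level
        for model, build in (("GNM", kirchhoff), ("ANM", hessian)):
            cfg = ENMConfig(model)
            m0 = diagonalize(build(helix_nodes, cfg), model, cfg)
            m1 = diagonalize(build(rotated, cfg), model, cfg)
            f0 = square_fluctuations(m0).values
            f1 = square_fluctuations(m1).values
            assert np.abs(f0 - f1).max() < 1e-8, model
            c0 = cross_correlation(m0, 10).values
            c1 = cross_correlation(m1, 10).values
            assert np.abs(c0 - c1).max() < 1e-8, model

    def test_zero_mode_index_rejected(self, helix_gnm):
        with pytest.raises(InvalidModeError):
            square_fluctuations(helix_gnm, [0])

    def test_values_nonnegative(self, cage_gnm_l3, cage_anm_l3):
        for ms in (cage_gnm_l3, cage_anm_l3):
            assert square_fluctuations(ms).values.min() >= 0


class TestCrossCorrelation:
    def test_diagonal_is_one(self, helix_gnm, helix_anm):
        for ms in (helix_gnm, helix_anm):
            c = cross_correlation(ms, 20).values
            assert np.abs(np.diag(c) - 1.0).max() < 1e-10

    def test_values_bounded(self, helix_gnm, helix_anm):
        for ms in (helix_gnm, helix_anm):
            c = cross_correlation(ms, 20).values
            assert c.min() >= -1.0 - 1e-12
            assert c.max() <= 1.0 + 1e-12

    def test_too_many_modes_rejected(self, helix_gnm):
        with pytest.raises(InvalidArgumentError):
            cross_correlation(helix_gnm, helix_gnm.n_modes + 1)

    def test_edges_more_correlated_than_vertex_pairs(self, default_cage,
                                                     cage_gnm_l3):
        """Duplex edges move as blocks: same-edge node pairs correlate
        more strongly than pairs drawn from different vertices."""
        c = cross_correlation(cage_gnm_l3, 20).values
        meta = cage_gnm_l3.node_meta
        ann = default_cage.annotations
        edge_of = np.array(
            [ann[(m[0], m[1])].element_index
             if ann[(m[0], m[1])].region == "helix" else -1
             for m in meta])
        same_edge, cross_vertex = [], []
        rng = np.random.default_rng(5)
        idx = rng.choice(len(meta), 400, replace=False)
        for a in idx[:200]:
            for b in idx[200:]:
                if edge_of[a] == -1 or edge_of[b] == -1 or a == b:
                    continue
                if edge_of[a] == edge_of[b]:
                    same_edge.append(c[a, b])
                else:
                    cross_vertex.append(c[a, b])
        assert np.mean(same_edge) > np.mean(cross_vertex)
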
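"""Mode-derived analyses: overlaps, spectra shares, hinges, profiles, NMD."""
import numpy as np
import pytest

from nacage import (FluctuationProfile, collectivity, cumulative_overlap,
                    detect_hinges, export_nmd, fraction_of_variance,
                    hinge_linker_fraction, map_correlation, overlap,
                    overlap_map, per_residue_profile, profile_correlation,
                    read_nmd, rescale_profile, square_fluctuations,
                    strand_profile)
from nacage.enm import CorrelationMap, ModeSet
from nacage.errors import (InvalidArgumentError, UndefinedCorrelationError,
                           UnsupportedModeKindError)


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


class TestOverlap:
    def test_identity(self):
        u = unit([1, 2, 3, 4])
        assert overlap(u, u) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert overlap([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)

    def test_sign_invariant(self):
        u = unit([3, -1, 2])
        assert overlap(u, -u) == pytest.approx(1.0)

    def test_non_unit_rejected(self):
        with pytest.raises(InvalidArgumentError):
            overlap([1.0, 1.0], [1.0, 0.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            overlap([1.0, 0.0], [1.0, 0.0, 0.0])


class TestCumulativeOverlap:
    def test_complete_basis_reaches_one(self, rng):
        basis = np.linalg.qr(rng.standard_normal((8, 8)))[0]
        target = unit(rng.standard_normal(8))
        co = cumulative_overlap(basis, target)
        assert co[-1] == pytest.approx(1.0, abs=1e-8)

    def test_first_term_equals_overlap(self, helix_anm, rng):
        target = unit(rng.standard_normal(helix_anm.eigenvectors.shape[0]))
        co = cumulative_overlap(helix_anm.eigenvectors[:, :5], target)
        assert co[0] == pytest.approx(overlap(helix_anm.mode(1), target))

    def test_monotone_nondecreasing(self, cage_anm_l3, rng):
        target = unit(rng.standard_normal(cage_anm_l3.eigenvectors.shape[0]))
        co = cumulative_overlap(cage_anm_l3.eigenvectors[:, :20], target)
        assert np.all(np.diff(co) >= -1e-12)

    def test_own_mode_jumps_to_one(self, helix_anm):
        co = cumulative_overlap(helix_anm.eigenvectors[:, :10],
                                helix_anm.mode(4))
        assert co[2] < 1e-6
        assert np.all(co[3:] == pytest.approx(1.0, abs=1e-8))

    def test_non_orthonormal_rejected(self, rng):
        bad = rng.standard_normal((6, 3))
        with pytest.raises(InvalidArgumentError):
            cumulative_overlap(bad, unit(rng.standard_normal(6)))


class TestOverlapMap:
    def test_self_map_is_identity(self, helix_anm):
        om = overlap_map(helix_anm, helix_anm, 10)
        assert np.abs(om - np.eye(10)).max() < 1e-8


class TestFractionOfVariance:
    def test_sums_to_one(self, helix_gnm, helix_anm):
        for ms in (helix_gnm, helix_anm):
            assert fraction_of_variance(ms).sum() == pytest.approx(1.0)

    def test_nonincreasing_for_gnm(self, cage_gnm_l3):
        p = fraction_of_variance(cage_gnm_l3)
        assert np.all(np.diff(p) <= 1e-15)


class TestCollectivity:
    def test_uniform_mode_is_fully_collective(self):
        v = unit(np.ones(50))
        assert collectivity(v) == pytest.approx(1.0)

    def test_single_node_mode(self):
        v = np.zeros(50)
        v[17] = 1.0
        assert collectivity(v) == pytest.approx(1.0 / 50)

    def test_cage_slowest_anm_mode_collective(self, cage_anm_l3):
        k = collectivity(cage_anm_l3.mode(1), n_nodes=cage_anm_l3.n_nodes)
        assert k > 0.5

    def test_zero_vector_rejected(self):
        with pytest.raises(InvalidArgumentError):
            collectivity(np.zeros(10))


def profile(values, meta=None):
    return FluctuationProfile(values=np.asarray(values, dtype=float),
                              modes_used="all", node_meta=meta or [])


class TestRescale:
    def test_mean_matches_reference(self, rng):
        a = profile(rng.uniform(1, 2, 30))
        b = profile(rng.uniform(5, 9, 30))
        out = rescale_profile(a, b)
        assert out.values.mean() == pytest.approx(b.values.mean(),
                                                  abs=1e-10)

    def test_preserves_correlation(self, rng):
        a = profile(rng.uniform(1, 2, 30))
        b = profile(rng.uniform(5, 9, 30))
        c = rng.uniform(0, 1, 30)
        r0 = np.corrcoef(a.values, c)[0, 1]
        r1 = np.corrcoef(rescale_profile(a, b).values, c)[0, 1]
        assert r0 == pytest.approx(r1, abs=1e-12)

    def test_identity(self, rng):
        a = profile(rng.uniform(1, 2, 30))
        assert np.allclose(rescale_profile(a, a).values, a.values)


class TestProfileCorrelation:
    def test_self_correlation(self, rng):
        a = profile(rng.uniform(1, 2, 30))
        assert profile_correlation(a, a) == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        a = profile(rng.uniform(1, 2, 30))
        b = profile(3.0 * a.values + 2.0)
        assert profile_correlation(a, b) == pytest.approx(1.0)

    def test_constant_profile_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            profile_correlation(profile(np.ones(10)),
                                profile(np.arange(10.0)))

    def test_levels_reduced_per_residue(self, helix_gnm):
        """A 3-node profile correlates with itself exactly after the
        per-residue reduction, whatever the node multiplicity."""
        f = square_fluctuations(helix_gnm)
        assert profile_correlation(f, f) == pytest.approx(1.0)
        assert len(per_residue_profile(f)) == 36


class TestMapCorrelation:
    def make_map(self, values):
        return CorrelationMap(values=values)

    def test_self(self, rng):
        m = rng.uniform(-1, 1, (10, 10))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        assert map_correlation(self.make_map(m),
                               self.make_map(m)) == pytest.approx(1.0)

    def test_antisymmetry(self, rng):
        m = rng.uniform(-1, 1, (10, 10))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        assert map_correlation(self.make_map(m),
                               self.make_map(-m)) == pytest.approx(-1.0)

    def test_shape_mismatch(self, rng):
        a = self.make_map(np.eye(5))
        b = self.make_map(np.eye(6))
        with pytest.raises(InvalidArgumentError):
            map_correlation(a, b)


def synthetic_gnm(values_per_mode, meta):
    """GNM-like ModeSet whose single-mode profiles equal given arrays."""
    n = len(meta)
    vecs = []
    for vals in values_per_mode:
        v = np.sqrt(np.asarray(vals, dtype=float))
        vecs.append(v / np.linalg.norm(v))
    return ModeSet(kind="GNM", eigenvalues=np.ones(len(vecs)),
                   eigenvectors=np.column_stack(vecs),
                   n_zero_excluded=1, node_meta=meta)


class TestHinges:
    def linear_meta(self, n, strand="A", region=None):
        return [(strand, i + 1, "P", region) for i in range(n)]

    def test_parabola_has_single_hinge(self):
        x = np.linspace(-1, 1, 41)
        meta = self.linear_meta(41)
        ms = synthetic_gnm([x ** 2 + 0.01], meta)
        hs = detect_hinges(ms, mode_indices=[1], circular=False)
        assert len(hs) == 1
        assert [h[2] for h in hs[0].hinge_nodes] == [21]

    def test_uniform_profile_has_no_hinges(self):
        meta = self.linear_meta(30)
        ms = synthetic_gnm([np.ones(30)], meta)
        hs = detect_hinges(ms, mode_indices=[1], circular=False)
        assert hs[0].hinge_nodes == []

    def test_invariant_to_profile_scale(self, cage_gnm_l3):
        a = detect_hinges(cage_gnm_l3)
        scaled = ModeSet(kind="GNM",
                         eigenvalues=cage_gnm_l3.eigenvalues,
                         eigenvectors=cage_gnm_l3.eigenvectors,
                         n_zero_excluded=1,
                         node_meta=cage_gnm_l3.node_meta, kT_scale=7.5)
        b = detect_hinges(scaled)
        assert [h.hinge_nodes for h in a] == [h.hinge_nodes for h in b]

    def test_cage_hinges_cluster_at_linkers(self, cage_gnm_l3):
        hs = detect_hinges(cage_gnm_l3)
        assert sum(len(h.hinge_nodes) for h in hs) > 0
        assert hinge_linker_fraction(hs, cage_gnm_l3.node_meta) >= 0.7

    def test_bad_parameters_rejected(self, cage_gnm_l3):
        with pytest.raises(InvalidArgumentError):
            detect_hinges(cage_gnm_l3, window=0)
        with pytest.raises(InvalidArgumentError):
            detect_hinges(cage_gnm_l3, percentile=100.0)


class TestStrandProfile:
    def test_level1_is_reindexing(self, default_cage):
        from nacage import ENMConfig, diagonalize, kirchhoff, select_nodes
        nodes = select_nodes(default_cage, 1)
        cfg = ENMConfig("GNM")
        ms = diagonalize(kirchhoff(nodes, cfg), "GNM", cfg,
                         node_meta=nodes.node_meta)
        f = square_fluctuations(ms)
        resi, vals = strand_profile(f, "S1")
        per_strand = [v for v, m in zip(f.values, ms.node_meta)
                      if m[0] == "S1"]
        assert np.array_equal(vals, per_strand)

    def test_level3_averages_three_nodes(self, cage_gnm_l3):
        f = square_fluctuations(cage_gnm_l3)
        resi, vals = strand_profile(f, "S1")
        by_res = {}
        for v, (sid, r, _, _) in zip(f.values, cage_gnm_l3.node_meta):
            if sid == "S1":
                by_res.setdefault(r, []).append(v)
        assert vals[0] == pytest.approx(np.mean(by_res[resi[0]]))
        assert len(vals) == 69

    def test_isolated_helix_tails_most_mobile(self, helix_gnm):
        """An unconstrained duplex frays at its ends: per-residue
        fluctuations peak at the termini and dip in the centre."""
        f = square_fluctuations(helix_gnm)
        _, vals = strand_profile(f, "A")
        centre = vals[6:12].mean()
        assert vals[0] > centre
        assert vals[-1] > centre

    def test_unknown_strand(self, cage_gnm_l3):
        f = square_fluctuations(cage_gnm_l3)
        with pytest.raises(InvalidArgumentError):
            strand_profile(f, "nope")


class TestNMD:
    def test_round_trip(self, tmp_path, helix_anm, helix_nodes):
        path = tmp_path / "modes.nmd"
        export_nmd(helix_anm, helix_nodes, path, n_modes=5)
        coords, scales, vectors = read_nmd(path)
        assert coords == pytest.approx(
            helix_nodes.positions.ravel(), abs=5e-4)
        assert vectors.shape[1] == 5
        for k in range(5):
            dot = abs(np.dot(vectors[:, k], helix_anm.mode(k + 1)))
            assert dot == pytest.approx(1.0, abs=1e-5)

    def test_gnm_not_exportable(self, tmp_path, helix_gnm, helix_nodes):
        with pytest.raises(UnsupportedModeKindError):
            export_nmd(helix_gnm, helix_nodes, tmp_path / "x.nmd")

    def test_mode_record_count(self, tmp_path, helix_anm, helix_nodes):
        path = tmp_path / "three.nmd"
        export_nmd(helix_anm, helix_nodes, path, n_modes=3)
        n_modes = sum(1 for line in path.read_text().splitlines()
                      if line.startswith("mode "))
        assert n_modes == 3
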
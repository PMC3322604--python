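import numpy as np
import pytest

from ncsx.harness import SyntheticSpec, generate_synthetic_multimer
from ncsx.ncs_detection import (
    DetectionConfig,
    cluster_rotations,
    enumerate_stretch_matches,
    filter_helix_only,
    is_helical_window,
)
from ncsx.superposition import RigidTransform, rotation_angle_between, superpose_lsq

from conftest import coil, make_fragment, make_model


def translated_copy_model(n=12, shift=60.0, seed=0):
    a = coil(n, seed)
    frag_a = make_fragment(a, 0, "A")
    frag_b = make_fragment(a + np.array([shift, 0, 0]), 1, "B")
    return make_model(frag_a, frag_b)


class TestEnumerateStretchMatches:
    def test_translated_copies_match_on_the_diagonal_only(self):
        """Count verified against exhaustive window enumeration."""
        model = translated_copy_model(n=12)
        cfg = DetectionConfig(stretch_length=10, rmsd_threshold=0.4)
        matches = enumerate_stretch_matches(model, cfg)

        # independent count: superpose all window pairs directly
        a = model.fragments[0].ca_coords
        b = model.fragments[1].ca_coords
        expected = sum(
            superpose_lsq(a[i:i + 10], b[j:j + 10]).rmsd < 0.4
            for i in range(3) for j in range(3)
        )
        assert expected == 3          # only register-aligned windows agree
        assert len(matches) == 2 * expected
        for m in matches:
            assert m.rmsd < 1e-9
            assert m.start_a == m.start_b

    def test_unrelated_coils_produce_no_matches(self):
        frag_a = make_fragment(coil(20, seed=11), 0, "A")
        frag_b = make_fragment(coil(20, seed=12) + 50.0, 1, "B")
        cfg = DetectionConfig(stretch_length=10, rmsd_threshold=0.4)
        assert enumerate_stretch_matches(make_model(frag_a, frag_b), cfg) == []

    def test_pentamer_all_subunit_pairs_match(self, pentamer_model):
        cfg = DetectionConfig(stretch_length=20, rmsd_threshold=0.4)
        matches = enumerate_stretch_matches(pentamer_model, cfg)
        pairs = {(m.frag_a, m.frag_b) for m in matches}
        assert pairs == {(i, j) for i in range(5) for j in range(5) if i != j}

    def test_short_fragments_are_excluded(self):
        frag_a = make_fragment(coil(4, seed=0), 0, "A")
        frag_b = make_fragment(coil(4, seed=0) + 40.0, 1, "B")
        cfg = DetectionConfig(stretch_length=3, rmsd_threshold=0.5)
        assert enumerate_stretch_matches(make_model(frag_a, frag_b), cfg) == []

    def test_resolution_rule_for_threshold(self):
        cfg = DetectionConfig()
        assert cfg.resolve_rmsd_threshold(make_model(resolution=2.0)) == 0.4
        assert cfg.resolve_rmsd_threshold(make_model(resolution=2.79)) == 0.4
        assert cfg.resolve_rmsd_threshold(make_model(resolution=2.8)) == 0.5
        assert cfg.resolve_rmsd_threshold(make_model(resolution=3.2)) == 0.5
        assert cfg.resolve_rmsd_threshold(make_model()) == 0.5

    def test_match_threshold_is_honoured(self):
        """A pair just over the acceptance threshold is rejected, just under kept."""
        base = coil(10, seed=5)
        for target, expect in [(0.395, 1), (0.405, 0)]:
            rng = np.random.default_rng(1)
            noise = rng.normal(size=base.shape)
            noise -= noise.mean(axis=0)
            # scale noise so the *superposed* rmsd hits the target
            pert = base + noise
            r = superpose_lsq(pert, base).rmsd
            pert = base + noise * (target / r)
            # iterate once more; superposition makes scaling mildly nonlinear
            pert = base + noise * (target / r) * (
                target / superpose_lsq(pert, base).rmsd)
            frag_a = make_fragment(base, 0, "A")
            frag_b = make_fragment(pert + 50.0, 1, "B")
            cfg = DetectionConfig(stretch_length=10, rmsd_threshold=0.4)
            got = enumerate_stretch_matches(make_model(frag_a, frag_b), cfg)
            assert len(got) == 2 * expect, (target, [m.rmsd for m in got])


class TestClusterRotations:
    def _matches_with_rotations(self, angles):
        """Synthetic matches whose transforms have the given rotations about z."""
        out = []
        base = coil(10, seed=3)
        for k, ang in enumerate(angles):
            t = RigidTransform.from_axis_angle([0, 0, 1], ang)
            frag_a = make_fragment(base, 2 * k, "A")
            frag_b = make_fragment(t.apply(base), 2 * k + 1, "B")
            m = enumerate_stretch_matches(
                make_model(frag_a, frag_b),
                DetectionConfig(stretch_length=10, rmsd_threshold=0.4))
            for mm in m:
                if mm.frag_a == 2 * k:       # keep one direction
                    out.append(mm)
        return out

    def test_single_rotation_single_cluster(self):
        matches = self._matches_with_rotations([30.0, 30.0, 30.0])
        clusters = cluster_rotations(matches, DetectionConfig())
        assert len(clusters) == 1 and clusters[0].size == 3

    def test_rotations_72_degrees_apart_split(self):
        matches = self._matches_with_rotations([30.0, 102.0])
        clusters = cluster_rotations(matches, DetectionConfig())
        assert len(clusters) == 2

    def test_cluster_angle_boundary(self):
        """4.9 degrees joins a cluster; 5.1 degrees founds a new one."""
        joined = self._matches_with_rotations([30.0, 34.9])
        split = self._matches_with_rotations([30.0, 35.1])
        assert len(cluster_rotations(joined, DetectionConfig())) == 1
        assert len(cluster_rotations(split, DetectionConfig())) == 2

    def test_partition_property(self, pentamer_model):
        cfg = DetectionConfig(stretch_length=20, rmsd_threshold=0.4)
        matches = enumerate_stretch_matches(pentamer_model, cfg)
        clusters = cluster_rotations(matches, cfg)
        assert sum(c.size for c in clusters) == len(matches)

    def test_pentamer_representative_angles(self, pentamer_model):
        cfg = DetectionConfig(stretch_length=20, rmsd_threshold=0.4)
        clusters = cluster_rotations(enumerate_stretch_matches(pentamer_model, cfg),
                                     cfg)
        angles = sorted({round(c.angle_deg, 3) for c in clusters})
        assert np.allclose(angles, [72.0, 144.0], atol=0.1)

    def test_every_cluster_has_inverse_partner(self, pentamer_model):
        cfg = DetectionConfig(stretch_length=20, rmsd_threshold=0.4)
        clusters = cluster_rotations(enumerate_stretch_matches(pentamer_model, cfg),
                                     cfg)
        for c in clusters:
            inv = c.representative.inverse()
            assert any(
                rotation_angle_between(inv.quaternion,
                                       other.representative.quaternion) < 1.0
                for other in clusters
            )

    def test_shuffle_invariance_when_well_separated(self):
        matches = self._matches_with_rotations([10.0, 10.5, 50.0, 50.8, 120.0])
        ref = cluster_rotations(matches, DetectionConfig())
        ref_sizes = sorted(c.size for c in ref)
        rng = np.random.default_rng(0)
        for _ in range(5):
            shuffled = list(matches)
            rng.shuffle(shuffled)
            got = cluster_rotations(shuffled, DetectionConfig())
            assert sorted(c.size for c in got) == ref_sizes


class TestHelixFilter:
    def _ideal_helix(self, n):
        from ncsx.harness import _helix
        return _helix(n, np.zeros(3), 1)

    def test_helix_fingerprint(self):
        assert is_helical_window(self._ideal_helix(10))
        assert not is_helical_window(coil(10, seed=2))

    def test_helix_helix_match_removed_coil_kept(self):
        helix = self._ideal_helix(10)
        model_h = make_model(make_fragment(helix, 0, "A"),
                             make_fragment(helix + 40.0, 1, "B"))
        cfg = DetectionConfig(stretch_length=10, rmsd_threshold=0.4)
        matches_h = enumerate_stretch_matches(model_h, cfg)
        assert matches_h and filter_helix_only(matches_h, model_h) == []

        model_c = translated_copy_model(n=10, seed=7)
        matches_c = enumerate_stretch_matches(model_c, cfg)
        assert filter_helix_only(matches_c, model_c) == matches_c

    def test_long_matches_survive_the_filter(self):
        helix = self._ideal_helix(20)
        model = make_model(make_fragment(helix, 0, "A"),
                           make_fragment(helix + 40.0, 1, "B"))
        cfg = DetectionConfig(stretch_length=20, rmsd_threshold=0.4)
        matches = enumerate_stretch_matches(model, cfg)
        assert matches
        kept = filter_helix_only(matches, model, max_length=10)
        assert kept == matches
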
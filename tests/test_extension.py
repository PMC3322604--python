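import numpy as np
import pytest

from ncsx.extension import (
    CLASH_DISTANCE,
    clash_filter,
    extend_match,
    transform_tails,
)
from ncsx.model_io import AtomRecord, Residue
from ncsx.ncs_detection import DetectionConfig, enumerate_stretch_matches
from ncsx.pipeline import run_pipeline
from ncsx.superposition import superpose_lsq

from conftest import coil, make_fragment, make_model


def match_between(model, stretch, threshold=0.4, frag_a=0, start_a=None):
    cfg = DetectionConfig(stretch_length=stretch, rmsd_threshold=threshold)
    matches = enumerate_stretch_matches(model, cfg)
    sel = [m for m in matches if m.frag_a == frag_a]
    if start_a is not None:
        sel = [m for m in sel if m.start_a == start_a]
    return sel[0]


class TestExtendMatch:
    def test_exact_copies_extend_to_full_overlap(self):
        a = coil(30, seed=1)
        model = make_model(make_fragment(a, 0, "A"),
                           make_fragment(a + 60.0, 1, "B"))
        m = match_between(model, 10, start_a=10)
        em = extend_match(m, model)
        assert em is not None
        assert em.l_ext == 30
        assert em.rmsd_ext < 1e-9
        assert (em.ext_start_a, em.ext_end_a) == (0, 29)

    def test_growth_stops_at_divergence_point(self):
        """Copies agree over the first 20 residues then drift hard."""
        a = coil(30, seed=2)
        b = a.copy()
        rng = np.random.default_rng(3)
        drift = rng.normal(size=(10, 3))
        drift /= np.linalg.norm(drift, axis=1, keepdims=True)
        b[20:] += drift * (8.0 * np.arange(1, 11))[:, None]
        model = make_model(make_fragment(a, 0, "A"),
                           make_fragment(b + 80.0, 1, "B"))
        m = match_between(model, 10, start_a=5)
        em = extend_match(m, model)
        assert em is not None
        assert em.ext_start_a == 0       # the agreeing side grows to the end
        # stepwise oracle: regrow the diverging side one residue at a time
        end = 14
        while end < 29:
            r = superpose_lsq(a[0:end + 2], b[0:end + 2]).rmsd
            if r > 0.2 * (end + 2):
                break
            end += 1
        assert em.ext_end_a == end
        # the tolerance loosens with length, so the stop lies at most a few
        # residues past the onset of divergence at residue 21
        assert 19 <= end <= 24

    def test_initial_violation_rejects_match(self):
        """A match whose starting window already exceeds 0.2*L is dropped."""
        from ncsx.ncs_detection import StretchMatch
        a = coil(12, seed=4)
        b = coil(12, seed=5) + 50.0
        model = make_model(make_fragment(a, 0, "A"), make_fragment(b, 1, "B"))
        res = superpose_lsq(a[0:5], b[0:5])
        assert res.rmsd > 0.2 * 5   # unrelated coils: way over threshold
        m = StretchMatch(0, 0, 1, 0, 5, res)
        assert extend_match(m, model) is None

    def test_accepted_threshold_is_generous_at_initial_length(self):
        """rmsd 0.3 over a 10-residue window is far below 0.2*10 = 2 A."""
        a = coil(10, seed=6)
        rng = np.random.default_rng(7)
        noise = rng.normal(size=a.shape) * 0.15
        model = make_model(make_fragment(a, 0, "A"),
                           make_fragment(a + noise + 50.0, 1, "B"))
        m = match_between(model, 10, threshold=0.5)
        assert 0.0 < m.rmsd < 0.5
        em = extend_match(m, model)
        assert em is not None and em.l_ext == 10


class TestTransformTails:
    def test_longer_fragment_donates_both_tails(self):
        """A spans 1-40; B holds only the copy of 10-30 and gains both ends."""
        a = coil(40, seed=8)
        model = make_model(
            make_fragment(a, 0, "A", start_index=1),
            make_fragment(a[9:30] + 70.0, 1, "B", start_index=10),
        )
        m = match_between(model, 10, start_a=12)
        em = extend_match(m, model)
        assert (em.ext_start_a, em.ext_end_a) == (9, 29)
        cands = transform_tails(em, model)
        assert {c.side for c in cands} == {"n_terminal", "c_terminal"}
        for c in cands:
            assert c.target_fragment == 1
            idx = [r.index for r in c.residues]
            assert idx == (list(range(1, 10)) if c.side == "n_terminal"
                           else list(range(31, 41)))

    def test_congruent_fragments_have_no_tails(self):
        a = coil(20, seed=9)
        model = make_model(make_fragment(a, 0, "A"),
                           make_fragment(a + 50.0, 1, "B"))
        em = extend_match(match_between(model, 10, start_a=0), model)
        assert transform_tails(em, model) == []

    def test_candidates_do_not_duplicate_target_residues(self):
        a = coil(40, seed=10)
        model = make_model(
            make_fragment(a, 0, "A", start_index=1),
            make_fragment(a[9:30] + 70.0, 1, "B", start_index=10),
        )
        em = extend_match(match_between(model, 10, start_a=15), model)
        target_idx = {r.index for r in model.fragment(1).residues}
        for c in transform_tails(em, model):
            assert target_idx.isdisjoint({r.index for r in c.residues})

    def test_proposed_ca_spacing_is_protein_like(self):
        a = coil(40, seed=11)
        model = make_model(
            make_fragment(a, 0, "A", start_index=1),
            make_fragment(a[:25] + 70.0, 1, "B", start_index=1),
        )
        em = extend_match(match_between(model, 10, start_a=5), model)
        for c in transform_tails(em, model):
            ca = c.ca_coords
            d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
            assert ((d >= 2.9) & (d <= 4.5)).all()


class TestClashFilter:
    def _candidate_at(self, positions, target=1):
        residues = []
        for i, p in enumerate(positions):
            atom = AtomRecord("B", 100 + i, "ALA", "CA", np.asarray(p, float), True)
            residues.append(Residue(100 + i, "ALA", np.asarray(p, float), [atom]))
        from ncsx.extension import ExtensionCandidate
        return ExtensionCandidate(target_fragment=target, source_fragment=0,
                                  residues=residues, side="c_terminal",
                                  extended=None)

    def test_boundary_is_strict_at_0_7(self):
        base = coil(10, seed=12)
        model = make_model(make_fragment(base, 0, "A"))
        near = base[0] + np.array([0.69, 0, 0])
        far = base[0] + np.array([0.71, 0, 0])
        assert clash_filter(self._candidate_at([near]), model).residues == []
        kept = clash_filter(self._candidate_at([far]), model)
        assert len(kept.residues) == 1 and kept.n_clash_deleted == 0

    def test_candidate_in_empty_space_untouched(self):
        model = make_model(make_fragment(coil(10, seed=13), 0, "A"))
        cand = self._candidate_at([[100, 100, 100], [103, 100, 100]])
        out = clash_filter(cand, model)
        assert len(out.residues) == 2 and out.n_clash_deleted == 0

    def test_residue_losing_ca_is_dropped_entirely(self):
        base = coil(10, seed=14)
        model = make_model(make_fragment(base, 0, "A"))
        pos = base[3] + np.array([0.1, 0, 0])
        cand = self._candidate_at([pos])
        cb = AtomRecord("B", 100, "ALA", "CB", pos + np.array([50, 0, 0]), False)
        cand.residues[0].atoms.append(cb)
        out = clash_filter(cand, model)
        assert out.residues == [] and out.n_clash_deleted == 1


def test_complete_exact_ncs_model_yields_no_candidates(pentamer_model):
    cfg = DetectionConfig(stretch_length=20, rmsd_threshold=0.4)
    result = run_pipeline(pentamer_model, cfg)
    assert result.found_ncs
    assert result.candidates == []


def test_extension_is_maximal(pentamer_model):
    """Growing any accepted overlap by one residue violates or runs off."""
    from ncsx.harness import ExclusionSpec, fragment_structure
    fragged, _ = fragment_structure(pentamer_model, ExclusionSpec(0.2, seed=5))
    cfg = DetectionConfig(stretch_length=10, rmsd_threshold=0.4)
    result = run_pipeline(fragged, cfg)
    assert result.extended
    for em in result.extended[:20]:
        fa = fragged.fragment(em.frag_a)
        fb = fragged.fragment(em.frag_b)
        for da0, da1 in [(-1, 0), (0, 1)]:
            a0, a1 = em.ext_start_a + da0, em.ext_end_a + da1
            b0, b1 = em.ext_start_b + da0, em.ext_end_b + da1
            if a0 < 0 or b0 < 0 or a1 >= len(fa) or b1 >= len(fb):
                continue   # runs off a fragment: maximal by construction
            grown = superpose_lsq(fa.ca_coords[a0:a1 + 1], fb.ca_coords[b0:b1 + 1])
            assert grown.rmsd > 0.2 * (a1 - a0 + 1)
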
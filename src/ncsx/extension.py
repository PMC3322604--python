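"""Growing accepted stretch matches and proposing NCS-transformed tails.

An accepted match is grown symmetrically along both chain directions; at
every step the superposition r.m.s.d. over the enlarged overlap of length
L_ext must stay within 0.2*L_ext Å, otherwise that side closes.  Once
growth finishes, the residues one fragment has beyond the shared overlap
("tails") are rigidly mapped through the overlap transform onto the other
fragment's frame, proposing new residues for it.  Proposed atoms closer
than 0.7 Å to any existing atom are deleted as stereochemical clashes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .model_io import PartialModel, Residue
from .ncs_detection import RotationCluster, StretchMatch
from .superposition import RigidTransform, superpose_lsq

#: Two atoms closer than this (Å) are a stereochemical clash.
CLASH_DISTANCE = 0.7

#: r.m.s.d. tolerance per residue of extended overlap length (Å/residue).
EXTENSION_RMSD_SLOPE = 0.2


@dataclass
class ExtendedMatch:
    """The maximal low-r.m.s.d. overlap grown from one stretch match."""

    base: StretchMatch
    ext_start_a: int
    ext_end_a: int        # inclusive offsets within fragment a
    ext_start_b: int
    ext_end_b: int
    l_ext: int
    rmsd_ext: float
    transform_ab: RigidTransform
    n_contributing_matches: int = 1
    cluster: Optional[RotationCluster] = None

    @property
    def frag_a(self) -> int:
        return self.base.frag_a

    @property
    def frag_b(self) -> int:
        return self.base.frag_b

    def overlap_key(self):
        return (self.frag_a, self.frag_b, self.ext_start_a, self.ext_end_a,
                self.ext_start_b, self.ext_end_b)


@dataclass
class ExtensionCandidate:
    """NCS-transformed tail residues proposed to extend one fragment."""

    target_fragment: int
    source_fragment: int
    residues: list[Residue]       # transformed, renumbered for the target
    side: str                     # "n_terminal" | "c_terminal"
    extended: ExtendedMatch
    cluster_ref: Optional[RotationCluster] = None
    weight: float = 0.0
    n_clash_deleted: int = 0

    @property
    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float)

    @property
    def centroid(self) -> np.ndarray:
        return self.ca_coords.mean(axis=0)

    @property
    def l_ext(self) -> int:
        return self.extended.l_ext

    @property
    def rmsd_ext(self) -> float:
        return self.extended.rmsd_ext

    @property
    def n_matches(self) -> int:
        return self.extended.n_contributing_matches


def _window_rmsd(fa_ca, fb_ca, a0, a1, b0, b1):
    res = superpose_lsq(fa_ca[a0:a1 + 1], fb_ca[b0:b1 + 1])
    return res


def extend_match(
    m: StretchMatch,
    model: PartialModel,
    rmsd_cap: Optional[float] = None,
) -> Optional[ExtendedMatch]:
    """Grow a match symmetrically while r.m.s.d. <= 0.2*L_ext Å.

    Sides alternate one residue per step; a side closes when its fragment
    is exhausted or when adding its residue pushes the recomputed overlap
    r.m.s.d. over the threshold.  Returns None ("not considered further")
    if the threshold is already violated at the initial length.
    """
    fa = model.fragment(m.frag_a)
    fb = model.fragment(m.frag_b)
    fa_ca, fb_ca = fa.ca_coords, fb.ca_coords
    a0, b0 = m.start_a, m.start_b
    a1, b1 = a0 + m.length - 1, b0 + m.length - 1

    def threshold(l_ext: int) -> float:
        thr = EXTENSION_RMSD_SLOPE * l_ext
        return min(thr, rmsd_cap) if rmsd_cap is not None else thr

    if m.rmsd > threshold(m.length):
        return None

    n_open = c_open = True
    while n_open or c_open:
        if n_open:
            if a0 > 0 and b0 > 0:
                res = _window_rmsd(fa_ca, fb_ca, a0 - 1, a1, b0 - 1, b1)
                if res.rmsd <= threshold(a1 - a0 + 2):
                    a0 -= 1
                    b0 -= 1
                else:
                    n_open = False
            else:
                n_open = False
        if c_open:
            if a1 < len(fa) - 1 and b1 < len(fb) - 1:
                res = _window_rmsd(fa_ca, fb_ca, a0, a1 + 1, b0, b1 + 1)
                if res.rmsd <= threshold(a1 - a0 + 2):
                    a1 += 1
                    b1 += 1
                else:
                    c_open = False
            else:
                c_open = False

    final = _window_rmsd(fa_ca, fb_ca, a0, a1, b0, b1)
    return ExtendedMatch(
        base=m,
        ext_start_a=a0, ext_end_a=a1,
        ext_start_b=b0, ext_end_b=b1,
        l_ext=a1 - a0 + 1,
        rmsd_ext=final.rmsd,
        transform_ab=final.transform,
    )


def group_extended_matches(extended: list[ExtendedMatch]) -> list[ExtendedMatch]:
    """Collapse matches that grew into the same overlap.

    Different initial windows along one true NCS relation all extend to
    the same maximal overlap; they are one piece of evidence counted by
    `n_contributing_matches`.
    """
    by_key: dict[tuple, ExtendedMatch] = {}
    counts: dict[tuple, int] = {}
    for em in extended:
        key = em.overlap_key()
        counts[key] = counts.get(key, 0) + em.n_contributing_matches
        if key not in by_key or em.rmsd_ext < by_key[key].rmsd_ext:
            by_key[key] = em
    out = []
    for key, em in by_key.items():
        out.append(replace(em, n_contributing_matches=counts[key]))
    return out


def contains_in_register(em: ExtendedMatch, m: StretchMatch) -> bool:
    """True if match `m` lies inside `em`'s overlap at the same register.

    Growth is monotone, so such a window would extend to the same maximal
    overlap; it is counted as contributing evidence instead of re-grown.
    """
    if (em.frag_a, em.frag_b) != (m.frag_a, m.frag_b):
        return False
    if m.start_a - em.ext_start_a != m.start_b - em.ext_start_b:
        return False
    return (em.ext_start_a <= m.start_a
            and m.start_a + m.length - 1 <= em.ext_end_a)


def transform_tails(
    em: ExtendedMatch, model: PartialModel
) -> list[ExtensionCandidate]:
    """Map unshared tail residues through the NCS operator.

    For each chain end where one fragment continues beyond the shared
    overlap and the other stops, the longer fragment's tail (all atoms)
    is rigidly transformed into the shorter fragment's frame; the
    transformed residues continue the target's author numbering outward.
    """
    fa = model.fragment(em.frag_a)
    fb = model.fragment(em.frag_b)
    t_ab = em.transform_ab
    t_ba = t_ab.inverse()
    # residue-number shift mapping fragment-a indices into b's numbering
    shift_ab = fb.residues[em.ext_start_b].index - fa.residues[em.ext_start_a].index
    cands: list[ExtensionCandidate] = []

    def make(source, target, tail_residues, transform, shift, side):
        if not tail_residues:
            return
        residues = [
            r.transformed(transform, new_index=r.index + shift,
                          new_chain=target.chain_id)
            for r in tail_residues
        ]
        cands.append(
            ExtensionCandidate(
                target_fragment=target.fragment_id,
                source_fragment=source.fragment_id,
                residues=residues,
                side=side,
                extended=em,
                cluster_ref=em.cluster,
            )
        )

    # N-terminal side
    a_has_n = em.ext_start_a > 0
    b_has_n = em.ext_start_b > 0
    if a_has_n and not b_has_n:
        make(fa, fb, fa.residues[:em.ext_start_a], t_ab, shift_ab, "n_terminal")
    elif b_has_n and not a_has_n:
        make(fb, fa, fb.residues[:em.ext_start_b], t_ba, -shift_ab, "n_terminal")

    # C-terminal side
    a_has_c = em.ext_end_a < len(fa) - 1
    b_has_c = em.ext_end_b < len(fb) - 1
    if a_has_c and not b_has_c:
        make(fa, fb, fa.residues[em.ext_end_a + 1:], t_ab, shift_ab, "c_terminal")
    elif b_has_c and not a_has_c:
        make(fb, fa, fb.residues[em.ext_end_b + 1:], t_ba, -shift_ab, "c_terminal")
    return cands


def clash_filter(
    cand: ExtensionCandidate,
    model: PartialModel,
    extra_atoms: Optional[np.ndarray] = None,
    clash_distance: float = CLASH_DISTANCE,
) -> ExtensionCandidate:
    """Delete proposed atoms closer than `clash_distance` to the model.

    The check runs against every atom of every current fragment plus any
    `extra_atoms` (e.g. already-accepted higher-ranked candidates).  A
    residue that loses its Ca is dropped entirely.  The comparison is
    strict: an atom at exactly the clash distance survives.
    """
    existing = model.all_atom_coords()
    if extra_atoms is not None and len(extra_atoms):
        existing = np.vstack([existing, extra_atoms])
    if not len(existing):
        return cand
    tree = cKDTree(existing)

    n_deleted = 0
    new_residues: list[Residue] = []
    for res in cand.residues:
        kept_atoms = []
        for a in res.atoms:
            d, _ = tree.query(a.position)
            if d < clash_distance:
                n_deleted += 1
            else:
                kept_atoms.append(a)
        if any(a.is_ca for a in kept_atoms):
            new_residues.append(Residue(res.index, res.name, res.ca, kept_atoms))
    return replace(
        cand,
        residues=new_residues,
        n_clash_deleted=cand.n_clash_deleted + n_deleted,
    )
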
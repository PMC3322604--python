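"""Detection of NCS operators from partially built chain fragments.

Every fixed-length Ca stretch of every fragment is least-squares superposed
onto every stretch of the same length of every other fragment.  Pairs
below the resolution-dependent r.m.s.d. threshold (0.4 Å above 2.8 Å
resolution, 0.5 Å otherwise) are kept, and their rotations — compared as
quaternions — are clustered with a 5° tolerance.  Populated rotation
clusters are the candidate NCS operators; because matching is pairwise the
method sees both proper (cyclic) and improper (arbitrary) symmetry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model_io import MIN_FRAGMENT_LEN, CaFragment, PartialModel, average_fragment_length
from .superposition import (
    RigidTransform,
    SuperpositionResult,
    pairwise_window_rmsd,
    rotation_angle_between,
    superpose_lsq,
)

#: Resolution (Å) at which the stretch-match r.m.s.d. threshold switches.
RESOLUTION_SWITCH = 2.8
RMSD_THRESHOLD_HIGH_RES = 0.4   # resolution better (lower) than 2.8 Å
RMSD_THRESHOLD_LOW_RES = 0.5


@dataclass(frozen=True)
class StretchMatch:
    """A pair of equal-length Ca windows that superpose below threshold.

    `result.transform` maps the window of `frag_a` onto the window of
    `frag_b`; matches are stored once per ordered direction, since a→b and
    b→a carry mutually inverse operators.
    """

    frag_a: int
    start_a: int          # 0-based offset within fragment a
    frag_b: int
    start_b: int
    length: int
    result: SuperpositionResult

    @property
    def rmsd(self) -> float:
        return self.result.rmsd

    @property
    def quaternion(self) -> np.ndarray:
        return self.result.transform.quaternion

    def sort_key(self):
        return (self.result.rmsd, self.frag_a, self.start_a, self.frag_b, self.start_b)


@dataclass
class RotationCluster:
    """Stretch matches whose rotations agree within the angular tolerance."""

    members: list[StretchMatch]
    representative: RigidTransform
    is_translation: bool = False    # rotation ~identity: translational NCS
    s_cluster: Optional[int] = None
    s_ncs: Optional[int] = None

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def angle_deg(self) -> float:
        return self.representative.rotation_angle_deg


@dataclass
class DetectionConfig:
    """Knobs of the detection stage; `None` means the adaptive default."""

    stretch_length: Optional[int] = None     # None -> floor(avg fragment length), min 5
    rmsd_threshold: Optional[float] = None   # None -> by resolution rule
    cluster_angle: float = 5.0               # degrees
    remove_helix_only: bool = False
    allow_intra_fragment: bool = False
    min_fragment_len: int = MIN_FRAGMENT_LEN
    extension_rmsd_cap: Optional[float] = None  # optional cap on 0.2*L_ext (Å)

    def __post_init__(self):
        if self.stretch_length is not None and self.stretch_length < 3:
            raise ValueError("stretch_length must be >= 3")
        if self.rmsd_threshold is not None and self.rmsd_threshold <= 0:
            raise ValueError("rmsd_threshold must be positive")
        if self.cluster_angle <= 0:
            raise ValueError("cluster_angle must be positive")

    def resolve_stretch_length(self, model: PartialModel) -> int:
        if self.stretch_length is not None:
            return self.stretch_length
        return max(MIN_FRAGMENT_LEN, math.floor(average_fragment_length(model)))

    def resolve_rmsd_threshold(self, model: PartialModel) -> float:
        if self.rmsd_threshold is not None:
            return self.rmsd_threshold
        res = model.resolution
        if res is not None and res < RESOLUTION_SWITCH:
            return RMSD_THRESHOLD_HIGH_RES
        return RMSD_THRESHOLD_LOW_RES


def enumerate_stretch_matches(
    model: PartialModel, cfg: DetectionConfig
) -> list[StretchMatch]:
    """All ordered window pairs superposing below the r.m.s.d. threshold.

    Fragments shorter than the stretch length (or the minimum usable
    fragment length) take no part.  Each unordered window pair below
    threshold yields two matches, one per direction, with mutually inverse
    transforms.
    """
    L = cfg.resolve_stretch_length(model)
    thr = cfg.resolve_rmsd_threshold(model)
    eligible = [
        f for f in model.fragments
        if len(f) >= max(L, cfg.min_fragment_len)
    ]
    matches: list[StretchMatch] = []

    windows = {}
    for f in eligible:
        ca = f.ca_coords
        n_win = len(f) - L + 1
        windows[f.fragment_id] = np.stack([ca[i:i + L] for i in range(n_win)])

    def add_pair(fa: CaFragment, ia: int, fb: CaFragment, ib: int):
        res_ab = superpose_lsq(fa.window(ia, L), fb.window(ib, L))
        if res_ab.rmsd < thr:
            matches.append(StretchMatch(fa.fragment_id, ia, fb.fragment_id, ib, L, res_ab))
            inv = res_ab.transform.inverse()
            matches.append(
                StretchMatch(
                    fb.fragment_id, ib, fa.fragment_id, ia, L,
                    SuperpositionResult(inv, res_ab.rmsd, res_ab.n_points),
                )
            )

    for i, fa in enumerate(eligible):
        for fb in eligible[i + 1:]:
            grid = pairwise_window_rmsd(windows[fa.fragment_id], windows[fb.fragment_id])
            for ia, ib in zip(*np.nonzero(grid < thr)):
                add_pair(fa, int(ia), fb, int(ib))
        if cfg.allow_intra_fragment:
            grid = pairwise_window_rmsd(windows[fa.fragment_id], windows[fa.fragment_id])
            n_win = grid.shape[0]
            for ia in range(n_win):
                for ib in range(ia + L, n_win):   # non-overlapping windows only
                    if grid[ia, ib] < thr:
                        add_pair(fa, ia, fa, ib)
    return matches


def cluster_rotations(
    matches: list[StretchMatch], cfg: DetectionConfig
) -> list[RotationCluster]:
    """Greedy leader clustering of match rotations.

    Matches are visited in order of ascending r.m.s.d. (most reliable
    first); each joins the first cluster whose founding rotation lies
    within `cluster_angle`, else founds a new one.  The stored
    representative is then the medoid — the member minimising its maximal
    angle to all members.  Clusters come back sorted by size, descending.
    """
    clusters: list[list[StretchMatch]] = []
    leaders: list[np.ndarray] = []
    for m in sorted(matches, key=StretchMatch.sort_key):
        q = m.quaternion
        for i, lead in enumerate(leaders):
            if rotation_angle_between(q, lead) < cfg.cluster_angle:
                clusters[i].append(m)
                break
        else:
            clusters.append([m])
            leaders.append(q)

    out: list[RotationCluster] = []
    for members in clusters:
        medoid = _medoid(members)
        rep = medoid.result.transform
        out.append(
            RotationCluster(
                members=members,
                representative=rep,
                is_translation=rep.rotation_angle_deg < cfg.cluster_angle,
            )
        )
    out.sort(key=lambda c: -c.size)
    return out


def _medoid(members: list[StretchMatch]) -> StretchMatch:
    if len(members) == 1:
        return members[0]
    quats = np.array([m.quaternion for m in members])
    dots = np.abs(quats @ quats.T)
    angles = 2.0 * np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))
    worst = angles.max(axis=1)
    return members[int(np.argmin(worst))]


# ---------------------------------------------------------------------------
# helix-only filtering

#: Ca-geometry fingerprint of an alpha helix: i->i+3 and i->i+4 distances (Å).
HELIX_D13 = (4.5, 5.6)
HELIX_D14 = (5.7, 6.7)


def is_helical_window(coords: np.ndarray) -> bool:
    """True if every applicable residue fits the alpha-helix Ca fingerprint.

    A purely geometric criterion: d(Ca_i, Ca_i+3) in [4.5, 5.6] Å and
    d(Ca_i, Ca_i+4) in [5.7, 6.7] Å for all i the window admits.  Windows
    of fewer than 4 residues cannot be assessed and count as non-helical.
    """
    n = len(coords)
    if n < 4:
        return False
    d13 = np.linalg.norm(coords[3:] - coords[:-3], axis=1)
    if not ((d13 >= HELIX_D13[0]) & (d13 <= HELIX_D13[1])).all():
        return False
    if n >= 5:
        d14 = np.linalg.norm(coords[4:] - coords[:-4], axis=1)
        if not ((d14 >= HELIX_D14[0]) & (d14 <= HELIX_D14[1])).all():
            return False
    return True


def filter_helix_only(
    matches: list[StretchMatch],
    model: PartialModel,
    max_length: Optional[int] = None,
) -> list[StretchMatch]:
    """Drop short matches whose stretches are both entirely alpha-helical.

    Helices are ubiquitous structural motifs, so a helix-on-helix match
    carries little NCS evidence.  Matches longer than `max_length` (default:
    all initial matches are "short", having exactly the stretch length)
    are kept regardless.
    """
    kept = []
    for m in matches:
        if max_length is not None and m.length > max_length:
            kept.append(m)
            continue
        wa = model.fragment(m.frag_a).window(m.start_a, m.length)
        wb = model.fragment(m.frag_b).window(m.start_b, m.length)
        if is_helical_window(wa) and is_helical_window(wb):
            continue
        kept.append(m)
    return kept
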
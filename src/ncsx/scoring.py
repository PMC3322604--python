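"""Weighting and ranking of NCS extension candidates.

Each candidate's weight combines the support of its rotation cluster
(S_cluster: size relative to other clusters; S_NCS: size relative to the
expected extent of an NCS-related part of the structure; both 0-3), the
number of initial stretch matches behind the extended overlap, a scaling
coefficient C, and the extended-overlap r.m.s.d. in the denominator:

    W = C * (S_cluster + S_NCS) * N_matches / max(rmsd_ext, 0.01 A)

Weights typically fall between 0 and 100; they are an ordinal ranking
device, not calibrated probabilities.  Only a limited number of top-ranked
candidates (typically three) are fed back into model building.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .extension import ExtensionCandidate
from .model_io import PartialModel
from .ncs_detection import RotationCluster

#: Floor on the r.m.s.d. denominator (Å): exact synthetic NCS would
#: otherwise yield infinite weights.
RMSD_EXT_FLOOR = 0.01

#: Candidates whose Ca centroids lie within this distance (Å) are
#: duplicates of one another (same span reached from different copies).
DEDUP_CENTROID_DISTANCE = 1.0


@dataclass(frozen=True)
class WeightTerms:
    s_cluster: int
    s_ncs: int
    n_matches: int
    rmsd_ext: float
    l_ext: int
    c: float = 1.0

    def __post_init__(self):
        if self.s_cluster not in (0, 1, 2, 3) or self.s_ncs not in (0, 1, 2, 3):
            raise ValueError("S terms must be integers in 0..3")
        if self.n_matches < 1:
            raise ValueError("n_matches must be >= 1")


def compute_s_cluster(cluster: RotationCluster,
                      all_clusters: list[RotationCluster]) -> int:
    """Cluster size relative to the mean size over all clusters.

    0 below the mean; 1 at or above it; 2 at or above twice; 3 at or above
    three times (equality resolves upward).
    """
    if not all_clusters:
        raise ValueError("all_clusters must be non-empty")
    mean = float(np.mean([c.size for c in all_clusters]))
    size = cluster.size
    if size >= 3 * mean:
        return 3
    if size >= 2 * mean:
        return 2
    if size >= mean:
        return 1
    return 0


def compute_s_ncs(cluster: RotationCluster, expected_ncs_size: float) -> int:
    """Cluster size relative to the expected size of one NCS-related part.

    3 at or above the expected size, 2 at or above half, 1 at or above a
    quarter, else 0.
    """
    if expected_ncs_size <= 0:
        raise ValueError("expected_ncs_size must be positive")
    r = cluster.size / expected_ncs_size
    if r >= 1.0:
        return 3
    if r >= 0.5:
        return 2
    if r >= 0.25:
        return 1
    return 0


def infer_expected_ncs_size(
    model: PartialModel,
    clusters: list[RotationCluster],
    cluster_angle: float = 5.0,
) -> float:
    """Expected residue extent of one NCS-related part of the structure.

    Preference order: stated expectation (total residues / NCS order);
    then built residues / NCS-order hint; then built residues divided by
    (number of distinct non-identity rotation-angle groups + 1), a crude
    census of how many copies the detected operators imply.
    """
    if model.total_residues_expected and model.ncs_order_hint:
        return model.total_residues_expected / model.ncs_order_hint
    built = model.n_residues
    if model.ncs_order_hint:
        return built / max(2, model.ncs_order_hint)
    angles = sorted(
        c.angle_deg for c in clusters if not c.is_translation
    )
    groups = 0
    last = None
    for a in angles:
        if last is None or a - last > cluster_angle:
            groups += 1
            last = a
    return built / (groups + 1)


def compute_weight(t: WeightTerms) -> float:
    """W = C * (S_cluster + S_NCS) * N_matches / max(rmsd_ext, floor)."""
    denom = max(t.rmsd_ext, RMSD_EXT_FLOOR)
    return t.c * (t.s_cluster + t.s_ncs) * t.n_matches / denom


def score_candidates(
    cands: list[ExtensionCandidate],
    clusters: list[RotationCluster],
    model: PartialModel,
    c: float = 1.0,
    expected_ncs_size: Optional[float] = None,
) -> list[ExtensionCandidate]:
    """Fill in S terms on the clusters and the weight on every candidate."""
    if not cands:
        return cands
    if expected_ncs_size is None:
        expected_ncs_size = infer_expected_ncs_size(model, clusters)
    for cl in clusters:
        cl.s_cluster = compute_s_cluster(cl, clusters)
        cl.s_ncs = compute_s_ncs(cl, expected_ncs_size)
    for cand in cands:
        cl = cand.cluster_ref
        s_cluster = cl.s_cluster if cl is not None else 0
        s_ncs = cl.s_ncs if cl is not None else 0
        terms = WeightTerms(
            s_cluster=s_cluster, s_ncs=s_ncs,
            n_matches=cand.n_matches,
            rmsd_ext=cand.rmsd_ext, l_ext=cand.l_ext, c=c,
        )
        cand.weight = compute_weight(terms)
    return cands


def deduplicate(cands: list[ExtensionCandidate]) -> list[ExtensionCandidate]:
    """Keep the best of near-coincident candidates.

    Candidates are visited best-first; one whose Ca centroid lies within
    1.0 Å of an already-kept candidate's centroid is a duplicate proposal
    of the same span from a different NCS copy and is discarded.
    """
    kept: list[ExtensionCandidate] = []
    for cand in sorted(cands, key=_rank_key):
        if not len(cand.residues):
            continue
        c0 = cand.centroid
        if any(np.linalg.norm(c0 - k.centroid) < DEDUP_CENTROID_DISTANCE
               for k in kept):
            continue
        kept.append(cand)
    return kept


def _rank_key(cand: ExtensionCandidate):
    return (-cand.weight, -cand.l_ext, cand.target_fragment, cand.side)


def rank_and_select(
    cands: list[ExtensionCandidate], top_k: int = 3
) -> list[ExtensionCandidate]:
    """Deduplicate, sort by weight descending, return the first top_k.

    Ties break by larger extended overlap, then (target fragment, side).
    """
    unique = deduplicate(cands)
    unique.sort(key=_rank_key)
    return unique[:top_k]


def candidate_report(cands: list[ExtensionCandidate]) -> pd.DataFrame:
    """Tabular report of every candidate for the TSV output."""
    rows = []
    for i, cand in enumerate(sorted(cands, key=_rank_key)):
        cl = cand.cluster_ref
        rows.append({
            "candidate_id": i,
            "source_fragment": cand.source_fragment,
            "target_fragment": cand.target_fragment,
            "side": cand.side,
            "n_residues": len(cand.residues),
            "l_ext": cand.l_ext,
            "rmsd_ext": round(cand.rmsd_ext, 4),
            "s_cluster": cl.s_cluster if cl else 0,
            "s_ncs": cl.s_ncs if cl else 0,
            "n_matches": cand.n_matches,
            "weight": round(cand.weight, 3),
            "n_clash_deleted": cand.n_clash_deleted,
        })
    return pd.DataFrame(rows)
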
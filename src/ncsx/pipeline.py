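"""End-to-end extension pipeline shared by the CLI and the test harness.

detect stretch matches -> cluster rotations -> grow matches -> transform
tails -> clash-filter -> weight -> rank.  The harness and the CLI differ
only in how many ranked candidates they keep and in whether candidates are
merged back into the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .extension import (
    CLASH_DISTANCE,
    ExtendedMatch,
    ExtensionCandidate,
    clash_filter,
    contains_in_register,
    extend_match,
    group_extended_matches,
    transform_tails,
)
from .model_io import PartialModel, Residue, model_from_residues
from .ncs_detection import (
    DetectionConfig,
    RotationCluster,
    StretchMatch,
    cluster_rotations,
    enumerate_stretch_matches,
    filter_helix_only,
)
from .scoring import _rank_key, deduplicate, score_candidates


@dataclass
class PipelineResult:
    matches: list[StretchMatch]
    clusters: list[RotationCluster]
    extended: list[ExtendedMatch]
    candidates: list[ExtensionCandidate]   # scored, clash-filtered, deduplicated

    @property
    def found_ncs(self) -> bool:
        return bool(self.clusters)


def run_pipeline(
    model: PartialModel,
    cfg: Optional[DetectionConfig] = None,
    c: float = 1.0,
    clash_distance: float = CLASH_DISTANCE,
    expected_ncs_size: Optional[float] = None,
) -> PipelineResult:
    """One full detection + extension + scoring pass over the model.

    Candidates come back ranked best-first, already clash-filtered against
    the model and against every higher-ranked accepted candidate, and
    deduplicated by Ca-centroid proximity.  Callers apply their own cap
    (top-k feedback for model building, no cap for retrieval).
    """
    cfg = cfg or DetectionConfig()
    matches = enumerate_stretch_matches(model, cfg)
    if cfg.remove_helix_only:
        matches = filter_helix_only(matches, model,
                                    max_length=cfg.resolve_stretch_length(model))
    clusters = cluster_rotations(matches, cfg)

    extended: list[ExtendedMatch] = []
    by_pair: dict[tuple, list[ExtendedMatch]] = {}
    for ci, cluster in enumerate(clusters):
        for m in cluster.members:
            key = (m.frag_a, m.frag_b, ci)
            hit = next(
                (em for em in by_pair.get(key, ())
                 if contains_in_register(em, m)),
                None,
            )
            if hit is not None:
                hit.n_contributing_matches += 1
                continue
            em = extend_match(m, model, rmsd_cap=cfg.extension_rmsd_cap)
            if em is not None:
                em.cluster = cluster
                by_pair.setdefault(key, []).append(em)
                extended.append(em)
    extended = group_extended_matches(extended)

    raw: list[ExtensionCandidate] = []
    for em in extended:
        raw.extend(transform_tails(em, model))
    raw = score_candidates(raw, clusters, model, c=c,
                           expected_ncs_size=expected_ncs_size)

    # Best-first clash filtering: accepted candidates join the obstacle set
    # so mutually clashing proposals cannot both survive.
    accepted: list[ExtensionCandidate] = []
    accepted_atoms: list[np.ndarray] = []
    for cand in sorted(raw, key=_rank_key):
        extra = np.vstack(accepted_atoms) if accepted_atoms else None
        filtered = clash_filter(cand, model, extra_atoms=extra,
                                clash_distance=clash_distance)
        if not filtered.residues:
            continue
        accepted.append(filtered)
        accepted_atoms.append(
            np.array([a.position for r in filtered.residues for a in r.atoms])
        )
    accepted = deduplicate(accepted)
    return PipelineResult(matches=matches, clusters=clusters,
                          extended=extended, candidates=accepted)


def merge_candidates(
    model: PartialModel,
    cands: Iterable[ExtensionCandidate],
    allowed_positions: Optional[set[tuple[str, int]]] = None,
    tag_occupancy: bool = True,
) -> PartialModel:
    """Merge accepted candidate residues into the model and re-segment.

    Existing residues always win over proposals; proposals for positions
    outside `allowed_positions` (when given, e.g. the reference numbering
    in retrieval tests) are discarded.  Merged seed residues are tagged
    with occupancy 0.00 so downstream tools can recognise them.
    """
    by_pos: dict[tuple[str, int], Residue] = {}
    chain_of_frag = {f.fragment_id: f.chain_id for f in model.fragments}
    for f in model.fragments:
        for r in f.residues:
            by_pos[(f.chain_id, r.index)] = r
    for cand in cands:
        chain = chain_of_frag[cand.target_fragment]
        for res in cand.residues:
            key = (chain, res.index)
            if key in by_pos:
                continue
            if allowed_positions is not None and key not in allowed_positions:
                continue
            if tag_occupancy:
                atoms = [
                    type(a)(a.chain_id, a.residue_index, a.residue_name,
                            a.atom_name, a.position, a.is_ca, 0.0)
                    for a in res.atoms
                ]
                res = Residue(res.index, res.name, res.ca, atoms)
            by_pos[key] = res

    chains: dict[str, list[Residue]] = {}
    for (chain, idx) in sorted(by_pos):
        chains.setdefault(chain, []).append(by_pos[(chain, idx)])
    return model_from_residues(
        chains,
        resolution=model.resolution,
        total_residues_expected=model.total_residues_expected,
        ncs_order_hint=model.ncs_order_hint,
    )
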
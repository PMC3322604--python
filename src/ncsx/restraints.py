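"""NCS restraint generation for refinement.

Long, reliable overlaps between NCS-related fragments are turned into
restraint groups: main-chain atoms restrained at the `medium` class,
side-chain atoms at `loose`.  Only overlaps strictly longer than 15
residues between fragments docked into the sequence qualify — restraints
built on doubtful relations would do more harm than good.  The writer
emits REFMAC-style `ncsr` keyword lines plus a JSON sidecar; numeric
sigmas are left to the refinement program's defaults.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

from .extension import ExtendedMatch
from .model_io import PartialModel

#: An overlap must be strictly longer than this many residues to qualify.
MIN_RESTRAINT_OVERLAP = 15

MAIN_CHAIN_CLASS = "medium"
SIDE_CHAIN_CLASS = "loose"


@dataclass
class RestraintGroup:
    """Residue ranges related by one NCS operator.

    pairs: list of (chain_id, fragment_id, first_residue, last_residue),
    one entry per NCS-related copy of the span.
    """

    pairs: list[tuple[str, int, int, int]]
    main_chain_class: str = MAIN_CHAIN_CLASS
    side_chain_class: str = SIDE_CHAIN_CLASS
    min_overlap: int = MIN_RESTRAINT_OVERLAP

    def sort_key(self):
        return tuple(self.pairs)


def derive_ncs_restraints(
    extended: list[ExtendedMatch],
    model: PartialModel,
    min_overlap: int = MIN_RESTRAINT_OVERLAP,
) -> list[RestraintGroup]:
    """One group per qualifying extended overlap.

    Overlaps of `min_overlap` residues or fewer are excluded, as are
    overlaps touching any fragment not docked into the sequence.  The
    a->b / b->a bookkeeping duplicates collapse to one group.
    """
    seen: set[tuple] = set()
    groups: list[RestraintGroup] = []
    for em in extended:
        if em.l_ext <= min_overlap:
            continue
        fa = model.fragment(em.frag_a)
        fb = model.fragment(em.frag_b)
        if not (fa.docked_to_sequence and fb.docked_to_sequence):
            continue
        pair_a = (fa.chain_id, fa.fragment_id,
                  fa.residues[em.ext_start_a].index,
                  fa.residues[em.ext_end_a].index)
        pair_b = (fb.chain_id, fb.fragment_id,
                  fb.residues[em.ext_start_b].index,
                  fb.residues[em.ext_end_b].index)
        key = tuple(sorted([pair_a, pair_b]))
        if key in seen:
            continue
        seen.add(key)
        groups.append(RestraintGroup(pairs=sorted([pair_a, pair_b]),
                                     min_overlap=min_overlap))
    groups.sort(key=RestraintGroup.sort_key)
    return groups


# Table-driven keyword spelling so the writer can be retargeted to another
# refinement dialect without touching the logic.
_KEYWORD_TEMPLATE = (
    "ncsr span chain {chain_a} resi {a_first} {a_last} "
    "chain {chain_b} resi {b_first} {b_last} "
    "main {main} side {side}"
)


def format_group(group: RestraintGroup) -> str:
    (chain_a, _, a_first, a_last), (chain_b, _, b_first, b_last) = group.pairs
    return _KEYWORD_TEMPLATE.format(
        chain_a=chain_a, a_first=a_first, a_last=a_last,
        chain_b=chain_b, b_first=b_first, b_last=b_last,
        main=group.main_chain_class, side=group.side_chain_class,
    )


def write_refmac_keywords(groups: list[RestraintGroup], path) -> None:
    """Write one keyword line per group (sorted, bit-stable) + JSON sidecar."""
    path = Path(path)
    if not groups:
        warnings.warn("no NCS restraint groups to write; writing empty file")
        path.write_text("")
        return
    lines = [format_group(g) for g in sorted(groups, key=RestraintGroup.sort_key)]
    path.write_text("\n".join(lines) + "\n")
    sidecar = path.with_suffix(path.suffix + ".json")
    payload = [
        {
            "pairs": [list(p) for p in g.pairs],
            "main_chain_class": g.main_chain_class,
            "side_chain_class": g.side_chain_class,
        }
        for g in sorted(groups, key=RestraintGroup.sort_key)
    ]
    sidecar.write_text(json.dumps(payload, indent=2) + "\n")


def parse_refmac_keywords(path) -> list[RestraintGroup]:
    """Re-parse a keyword file written by `write_refmac_keywords`.

    Round-trip partner used to verify the writer's output is well formed.
    Fragment ids are not encoded in the keyword dialect and come back as -1.
    """
    groups = []
    for line in Path(path).read_text().splitlines():
        tok = line.split()
        if not tok or tok[0] != "ncsr":
            continue
        # ncsr span chain A resi 10 40 chain B resi 10 40 main medium side loose
        chain_a, a_first, a_last = tok[3], int(tok[5]), int(tok[6])
        chain_b, b_first, b_last = tok[8], int(tok[10]), int(tok[11])
        groups.append(RestraintGroup(
            pairs=[(chain_a, -1, a_first, a_last), (chain_b, -1, b_first, b_last)],
            main_chain_class=tok[13], side_chain_class=tok[15],
        ))
    return groups
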
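"""Reading, writing and fragmenting atomic protein models.

A partial model is held as a list of :class:`CaFragment` objects — maximal
runs of residues with consecutive author numbering and bonded Ca-Ca
geometry.  gemmi does the heavy lifting for the PDB/mmCIF dialects; this
module owns the fragmentation rules and the Ca-trace view the rest of the
package works on.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import gemmi
import numpy as np

#: Ca-Ca distance beyond which a chain is considered broken (Å).  Covers
#: both trans (~3.8 Å) and cis (~2.9 Å) peptides with margin.
CA_BREAK_DISTANCE = 4.5

#: Fragments shorter than this are carried along but excluded from NCS
#: matching — very short fragments contribute noise, not operators.
MIN_FRAGMENT_LEN = 5


class EmptyModelError(ValueError):
    """Model contains no Ca atoms."""


class ModelFormatError(ValueError):
    """File could not be parsed under the requested dialect."""


@dataclass(frozen=True)
class AtomRecord:
    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    position: np.ndarray
    is_ca: bool = False
    occupancy: float = 1.0

    def moved_to(self, position: np.ndarray) -> "AtomRecord":
        return AtomRecord(
            self.chain_id, self.residue_index, self.residue_name,
            self.atom_name, np.asarray(position, dtype=float), self.is_ca,
            self.occupancy,
        )


@dataclass
class Residue:
    """One residue of a fragment: its Ca plus any further atoms."""

    index: int                    # author numbering
    name: str                     # 3-letter code
    ca: np.ndarray                # Ca position, Å
    atoms: list[AtomRecord] = field(default_factory=list)  # includes the Ca

    def transformed(self, transform, new_index: Optional[int] = None,
                    new_chain: Optional[str] = None) -> "Residue":
        idx = self.index if new_index is None else new_index
        new_atoms = [
            AtomRecord(new_chain or a.chain_id, idx, a.residue_name,
                       a.atom_name, transform.apply(a.position), a.is_ca,
                       a.occupancy)
            for a in self.atoms
        ]
        return Residue(idx, self.name, transform.apply(self.ca), new_atoms)


@dataclass
class CaFragment:
    """A maximal unbroken run of residues from one chain."""

    fragment_id: int
    chain_id: str
    residues: list[Residue]
    docked_to_sequence: bool = True

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=float)

    @property
    def first_index(self) -> int:
        return self.residues[0].index

    @property
    def last_index(self) -> int:
        return self.residues[-1].index

    def window(self, start: int, length: int) -> np.ndarray:
        return self.ca_coords[start:start + length]


@dataclass
class PartialModel:
    fragments: list[CaFragment]
    resolution: Optional[float] = None
    total_residues_expected: Optional[int] = None
    ncs_order_hint: Optional[int] = None

    def __post_init__(self):
        ids = [f.fragment_id for f in self.fragments]
        if len(ids) != len(set(ids)):
            raise ValueError("fragment_ids must be unique")

    @property
    def n_residues(self) -> int:
        return sum(len(f) for f in self.fragments)

    def fragment(self, fragment_id: int) -> CaFragment:
        for f in self.fragments:
            if f.fragment_id == fragment_id:
                return f
        raise KeyError(f"no fragment {fragment_id}")

    def iter_atoms(self) -> Iterator[AtomRecord]:
        for f in self.fragments:
            for r in f.residues:
                yield from r.atoms

    def all_atom_coords(self) -> np.ndarray:
        coords = [a.position for a in self.iter_atoms()]
        return np.array(coords, dtype=float) if coords else np.empty((0, 3))

    def residue_map(self) -> dict[tuple[str, int], Residue]:
        """(chain_id, residue_index) -> Residue over all fragments."""
        out: dict[tuple[str, int], Residue] = {}
        for f in self.fragments:
            for r in f.residues:
                out[(f.chain_id, r.index)] = r
        return out


# ---------------------------------------------------------------------------
# segmentation

def split_into_fragments(
    residues: Iterable[Residue], chain_id: str, next_id: int
) -> tuple[list[CaFragment], int]:
    """Split an ordered residue run at numbering gaps or Ca-Ca breaks.

    Idempotent: residues already forming an unbroken run come back as one
    fragment.  Returns the fragments and the next free fragment id.
    """
    frags: list[CaFragment] = []
    current: list[Residue] = []
    for res in residues:
        if current:
            prev = current[-1]
            gap = res.index != prev.index + 1
            broken = np.linalg.norm(res.ca - prev.ca) > CA_BREAK_DISTANCE
            if gap or broken:
                frags.append(CaFragment(next_id, chain_id, current))
                next_id += 1
                current = []
        current.append(res)
    if current:
        frags.append(CaFragment(next_id, chain_id, current))
        next_id += 1
    return frags, next_id


def model_from_residues(
    chains: dict[str, list[Residue]], **model_kwargs
) -> PartialModel:
    """Build a PartialModel by segmenting per-chain residue lists."""
    frags: list[CaFragment] = []
    next_id = 0
    for chain_id in sorted(chains):
        new, next_id = split_into_fragments(chains[chain_id], chain_id, next_id)
        frags.extend(new)
    return PartialModel(fragments=frags, **model_kwargs)


# ---------------------------------------------------------------------------
# file I/O

def _detect_dialect(path: Path, dialect: Optional[str]) -> str:
    if dialect is not None:
        return dialect
    suffix = path.suffix.lower()
    return "mmcif" if suffix in {".cif", ".mmcif"} else "pdb"


def read_model(path, dialect: Optional[str] = None,
               resolution: Optional[float] = None) -> PartialModel:
    """Read a PDB or mmCIF file and segment it into Ca fragments.

    Only altloc '' or 'A' atoms are taken; residues without a Ca atom are
    dropped (they cannot carry the trace) and act as fragment breaks.
    """
    path = Path(path)
    fmt = _detect_dialect(path, dialect)
    try:
        if fmt == "mmcif":
            structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ModelFormatError(f"cannot parse {path} as {fmt}: {exc}") from exc

    if not structure or len(structure) == 0:
        raise EmptyModelError(f"{path}: no models in file")
    model = structure[0]

    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            ca = None
            atoms: list[AtomRecord] = []
            for atom in res:
                if atom.altloc not in ("", "\0", "A"):
                    continue
                pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                rec = AtomRecord(chain.name, res.seqid.num, res.name,
                                 atom.name, pos, atom.name == "CA")
                atoms.append(rec)
                if atom.name == "CA":
                    ca = pos
            if ca is None:
                continue
            residues.append(Residue(res.seqid.num, res.name, ca, atoms))
        if residues:
            chains.setdefault(chain.name, []).extend(residues)

    if not chains:
        raise EmptyModelError(f"{path}: model contains no Ca atoms")

    res_out = resolution
    if res_out is None and structure.resolution and structure.resolution > 0:
        res_out = float(structure.resolution)
    return model_from_residues(chains, resolution=res_out)


def write_model(model: PartialModel, path, dialect: Optional[str] = None,
                remarks: Optional[list[str]] = None) -> None:
    """Write the model; fragment boundaries survive a read/write round trip.

    Extension-candidate residues merged into the model should carry
    occupancy 0.00 (see `tag_occupancy` in the extension pipeline) so that
    downstream tools can treat them as seed coordinates; `remarks` lines
    document their provenance.
    """
    if not model.fragments:
        raise EmptyModelError("refusing to write an empty model")
    path = Path(path)
    fmt = _detect_dialect(path, dialect)

    structure = gemmi.Structure()
    structure.name = path.stem
    gmodel = gemmi.Model("1")
    by_chain: dict[str, list[CaFragment]] = {}
    for frag in model.fragments:
        by_chain.setdefault(frag.chain_id, []).append(frag)
    for chain_id in sorted(by_chain):
        chain = gemmi.Chain(chain_id)
        frags = sorted(by_chain[chain_id], key=lambda f: f.first_index)
        for frag in frags:
            for res in frag.residues:
                gres = gemmi.Residue()
                gres.name = res.name
                gres.seqid = gemmi.SeqId(res.index, " ")
                for a in res.atoms or [AtomRecord(chain_id, res.index, res.name,
                                                  "CA", res.ca, True)]:
                    gatom = gemmi.Atom()
                    gatom.name = a.atom_name
                    gatom.element = gemmi.Element(a.atom_name[:1])
                    gatom.pos = gemmi.Position(*a.position)
                    gatom.occ = a.occupancy
                    gres.add_atom(gatom)
                chain.add_residue(gres)
        gmodel.add_chain(chain)
    structure.add_model(gmodel)
    structure.setup_entities()

    if fmt == "mmcif":
        structure.make_mmcif_document().write_file(str(path))
    else:
        with open(path, "w") as fh:
            for line in remarks or []:
                fh.write(f"REMARK 350 {line}\n")
            fh.write(structure.make_pdb_string())


def average_fragment_length(model: PartialModel) -> float:
    """Arithmetic mean fragment length; feeds the default stretch length."""
    if not model.fragments:
        raise EmptyModelError("model has no fragments")
    return float(np.mean([len(f) for f in model.fragments]))


def chain_letters(n: int) -> list[str]:
    """A, B, ... Z, AA, AB ... — deterministic chain ids for n chains."""
    letters = list(string.ascii_uppercase)
    out = []
    for i in range(n):
        if i < 26:
            out.append(letters[i])
        else:
            out.append(letters[i // 26 - 1] + letters[i % 26])
    return out
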
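"""Structure and sequence I/O.

Reads and writes macromolecular structures in PDB format (via gemmi) and
protein sequences in FASTA (via Biopython), and exposes the atom-level
bookkeeping the conservation-enrichment statistics are built on: residue
indexing by author numbering and heavy-atom counting.

Conventions
-----------
* Author residue numbering (``res_seq`` plus insertion code) is the public
  residue identifier throughout; nothing is renumbered, because pocket-server
  outputs refer to author numbering.
* Heavy atoms only by default everywhere: crystal structures typically carry
  no hydrogens, and mixing hydrogen counts into the pocket statistics would
  make them incommensurable across inputs.
* Alternate locations are resolved to the highest-occupancy conformer
  (ties: first encountered).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Sequence, Union

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import IUPACData

#: (chain_id, author residue number, insertion code) — the public residue key.
ResidueId = tuple[str, int, str]

_THREE_TO_ONE = {k.upper(): v for k, v in IUPACData.protein_letters_3to1.items()}

_HYDROGEN_ELEMENTS = {"H", "D"}


class PDBParseError(ValueError):
    """A PDB coordinate line could not be parsed; carries the line number."""


class EmptyStructureError(ValueError):
    """The source contained no atoms at all."""


class ChainNotFoundError(KeyError):
    pass


class ResidueNotFoundError(KeyError):
    pass


@dataclass
class AtomRecord:
    """One atom, with author identifiers and Cartesian coordinates in Å."""

    serial: int
    atom_name: str
    element: str
    chain_id: str
    res_name: str
    res_seq: int
    insertion_code: str = ""
    coords: np.ndarray = field(default_factory=lambda: np.zeros(3))
    is_hetero: bool = False
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element symbol")

    @property
    def residue_id(self) -> ResidueId:
        return (self.chain_id, self.res_seq, self.insertion_code)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN_ELEMENTS


@dataclass
class Structure:
    """An ordered atom collection for one model, indexed by residue.

    ``residue_index`` maps each polymer residue id to the positions of its
    atoms in ``atoms``; hetero atoms (ligands, waters) are kept in ``atoms``
    but never enter the residue index or polymer atom counts.
    """

    model_id: int
    atoms: list[AtomRecord]
    residue_index: dict[ResidueId, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.residue_index:
            self.residue_index = _build_residue_index(self.atoms)

    @property
    def hetero_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.is_hetero]

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for rid in self.residue_index:
            seen.setdefault(rid[0], None)
        return list(seen)

    def residues_of_chain(self, chain_id: str) -> list[ResidueId]:
        rids = [rid for rid in self.residue_index if rid[0] == chain_id]
        if not rids:
            raise ChainNotFoundError(f"chain {chain_id!r} not found")
        return rids

    def coords_array(self) -> np.ndarray:
        """(n_atoms, 3) float array of all atom coordinates, Å."""
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class ProteinSequence:
    """One-letter protein sequence with per-position residue identifiers."""

    id: str
    residues: str
    numbering: list[ResidueId] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.numbering:
            self.numbering = [("", i + 1, "") for i in range(len(self.residues))]
        if len(self.numbering) != len(self.residues):
            raise ValueError("numbering length must match sequence length")

    def __len__(self) -> int:
        return len(self.residues)


def _build_residue_index(atoms: Sequence[AtomRecord]) -> dict[ResidueId, list[int]]:
    index: dict[ResidueId, list[int]] = {}
    for i, atom in enumerate(atoms):
        if atom.is_hetero:
            continue
        index.setdefault(atom.residue_id, []).append(i)
    return index


def _as_text(source: Union[str, os.PathLike, IO[str]]) -> str:
    if hasattr(source, "read"):
        return source.read()
    text = os.fspath(source)
    if "\n" in text or not os.path.exists(text):
        # Raw PDB text is accepted directly; anything that is not an existing
        # path and has no newline is almost certainly a typo'd filename.
        if "\n" in text:
            return text
        raise FileNotFoundError(f"no such file: {text}")
    with open(text) as handle:
        return handle.read()


def _validate_coordinate_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line.rstrip("\n")) < 54:
            raise PDBParseError(f"line {lineno}: truncated coordinate record")
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: malformed coordinate field") from exc


def read_pdb(source: Union[str, os.PathLike, IO[str]]) -> list[Structure]:
    """Parse PDB text into one :class:`Structure` per MODEL.

    Altloc conformers are collapsed to the highest-occupancy atom (ties go to
    the first conformer encountered). HETATM records are kept with
    ``is_hetero`` set. Raises :class:`PDBParseError` with the offending line
    number on malformed fixed-width records and :class:`EmptyStructureError`
    when the source contains no atoms.
    """
    text = _as_text(source)
    _validate_coordinate_lines(text)
    st = gemmi.read_pdb_string(text)

    structures: list[Structure] = []
    for model_no, model in enumerate(st, start=1):
        atoms: list[AtomRecord] = []
        serial = 0
        for chain in model:
            for res in chain:
                chosen: dict[str, gemmi.Atom] = {}
                order: list[str] = []
                for atom in res:
                    prev = chosen.get(atom.name)
                    if prev is None:
                        chosen[atom.name] = atom
                        order.append(atom.name)
                    elif atom.occ > prev.occ:
                        chosen[atom.name] = atom
                for name in order:
                    atom = chosen[name]
                    serial += 1
                    atoms.append(
                        AtomRecord(
                            serial=serial,
                            atom_name=name,
                            element=atom.element.name,
                            chain_id=chain.name,
                            res_name=res.name,
                            res_seq=res.seqid.num,
                            insertion_code=(res.seqid.icode or " ").strip(),
                            coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                            is_hetero=(res.het_flag == "H"),
                            occupancy=atom.occ,
                            b_factor=atom.b_iso,
                        )
                    )
        structures.append(Structure(model_id=model_no, atoms=atoms))

    if not structures or all(not s.atoms for s in structures):
        raise EmptyStructureError("no atoms found in PDB source")
    return structures


def write_pdb(
    structures: Union[Structure, Iterable[Structure]],
    target: Optional[Union[str, os.PathLike, IO[str]]] = None,
) -> str:
    """Write one or more structures as (multi-model) PDB text.

    Returns the text; writes it to ``target`` (path or stream) when given.
    """
    if isinstance(structures, Structure):
        structures = [structures]
    st = gemmi.Structure()
    for s in structures:
        model = gemmi.Model(s.model_id)
        for atom in s.atoms:
            chain = model.find_chain(atom.chain_id)
            if chain is None:
                model.add_chain(gemmi.Chain(atom.chain_id))
                chain = model.find_chain(atom.chain_id)
            seqid = gemmi.SeqId(atom.res_seq, atom.insertion_code or " ")
            res = None
            if len(chain) > 0:
                last = chain[len(chain) - 1]
                if last.seqid == seqid and last.name == atom.res_name:
                    res = last
            if res is None:
                res = gemmi.Residue()
                res.name = atom.res_name
                res.seqid = seqid
                res.het_flag = "H" if atom.is_hetero else "A"
                chain.add_residue(res)
                res = chain[len(chain) - 1]
            g = gemmi.Atom()
            g.name = atom.atom_name
            g.element = gemmi.Element(atom.element)
            g.pos = gemmi.Position(*atom.coords)
            g.occ = atom.occupancy
            g.b_iso = atom.b_factor
            res.add_atom(g)
        st.add_model(model)
    st.setup_entities()
    text = st.make_pdb_string()
    if target is not None:
        if hasattr(target, "write"):
            target.write(text)
        else:
            with open(target, "w") as handle:
                handle.write(text)
    return text


def extract_sequence(s: Structure, chain: str) -> ProteinSequence:
    """One-letter sequence of a chain's polymer residues, in residue order.

    Nonstandard residues map to ``X`` (their heavy atoms still count in the
    atom statistics). Raises :class:`ChainNotFoundError` for unknown chains.
    """
    rids = s.residues_of_chain(chain)
    letters = []
    for rid in rids:
        res_name = s.atoms[s.residue_index[rid][0]].res_name
        letters.append(_THREE_TO_ONE.get(res_name.upper(), "X"))
    return ProteinSequence(id=f"model{s.model_id}_{chain}", residues="".join(letters), numbering=list(rids))


def count_atoms(
    s: Structure,
    residues: Optional[Iterable[ResidueId]] = None,
    include_hydrogens: bool = False,
) -> int:
    """Number of polymer atoms, heavy by default (T_a, P_a, TC_a substrate).

    Restricted to ``residues`` when given; hetero atoms never count.
    Raises :class:`ResidueNotFoundError` for identifiers absent from the
    structure.
    """
    if residues is None:
        positions: Iterable[int] = (i for idx in s.residue_index.values() for i in idx)
    else:
        positions_list: list[int] = []
        for rid in residues:
            rid = (rid[0], int(rid[1]), rid[2] if len(rid) > 2 else "")
            if rid not in s.residue_index:
                raise ResidueNotFoundError(f"residue {rid} not in structure")
            positions_list.extend(s.residue_index[rid])
        positions = positions_list
    n = 0
    for i in positions:
        if include_hydrogens or not s.atoms[i].is_hydrogen:
            n += 1
    return n


def read_fasta(source: Union[str, os.PathLike, IO[str]]) -> list[ProteinSequence]:
    """Read protein sequences from FASTA; numbering is sequential from 1."""
    if hasattr(source, "read"):
        handle: IO[str] = source  # type: ignore[assignment]
        records = list(SeqIO.parse(handle, "fasta"))
    else:
        records = list(SeqIO.parse(os.fspath(source), "fasta"))
    return [ProteinSequence(id=r.id, residues=str(r.seq).upper()) for r in records]


def write_fasta(
    sequences: Union[ProteinSequence, Iterable[ProteinSequence]],
    target: Union[str, os.PathLike, IO[str]],
) -> None:
    if isinstance(sequences, ProteinSequence):
        sequences = [sequences]
    records = [SeqRecord(Seq(p.residues), id=p.id, description="") for p in sequences]
    if hasattr(target, "write"):
        SeqIO.write(records, target, "fasta")
    else:
        with open(target, "w") as handle:
            SeqIO.write(records, handle, "fasta")
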
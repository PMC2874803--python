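"""Structure model: PDB reading, chain partitioning, atom classification.

A protein complex is held as a lightweight :class:`StructureModel` — ordered
chains of residues of heavy atoms.  The complex can be partitioned into its
two interacting sides so that every geometric feature can be computed both in
the *bound* state (full complex) and the *unbound* state (one side alone,
identical coordinates).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio.PDB import PDBParser

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "ComplexPartition",
    "EmptyStructureError",
    "MissingChainError",
    "read_pdb",
    "write_pdb",
    "partition",
    "classify_atom",
    "infer_element",
    "AA3",
]

#: The 20 standard three-letter residue codes.
AA3 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()

_WATER_NAMES = {"HOH", "WAT", "DOD"}
_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


class EmptyStructureError(ValueError):
    """Raised when a PDB file contains no usable ATOM records."""


class MissingChainError(KeyError):
    """Raised when a partition references a chain absent from the model."""


@dataclasses.dataclass(frozen=True)
class Atom:
    """A heavy atom with coordinates and crystallographic metadata."""

    name: str
    element: str
    coord: np.ndarray  # shape (3,), Å
    bfactor: float = 0.0  # temperature factor, Å²
    occupancy: float = 1.0
    altloc: str = ""
    serial: int = 0

    def __post_init__(self) -> None:
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError(f"atom {self.name}: coord must be 3 finite values")
        object.__setattr__(self, "coord", coord)
        if not self.element:
            object.__setattr__(self, "element", infer_element(self.name))


@dataclasses.dataclass
class Residue:
    """A residue: identity triple within a chain plus its heavy atoms."""

    chain_id: str
    seq_num: int
    icode: str
    aa_type: str  # three-letter code or "UNK"
    atoms: list[Atom]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def is_sparse(self) -> bool:
        """Fewer than 4 atoms present — features over present atoms only."""
        return len(self.atoms) < 4


@dataclasses.dataclass
class StructureModel:
    """An ordered collection of chains, each an ordered list of residues."""

    pdb_id: str
    chains: dict[str, list[Residue]]  # insertion-ordered

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains.values():
            yield from chain

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues():
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(res.n_atoms for res in self.residues())

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in model order."""
        if self.n_atoms == 0:
            return np.empty((0, 3))
        return np.array([a.coord for a in self.atoms()])

    def subset(self, chain_ids: Iterable[str]) -> "StructureModel":
        wanted = list(chain_ids)
        missing = [c for c in wanted if c not in self.chains]
        if missing:
            raise MissingChainError(
                f"chains {missing} not in model (has {self.chain_ids})"
            )
        return StructureModel(
            pdb_id=self.pdb_id,
            chains={c: self.chains[c] for c in self.chains if c in wanted},
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigid-body copy: x -> R x + t (used by invariance tests)."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        chains: dict[str, list[Residue]] = {}
        for cid, residues in self.chains.items():
            chains[cid] = [
                dataclasses.replace(
                    res,
                    atoms=[
                        dataclasses.replace(a, coord=rotation @ a.coord + translation)
                        for a in res.atoms
                    ],
                )
                for res in residues
            ]
        return StructureModel(self.pdb_id, chains)


@dataclasses.dataclass(frozen=True)
class ComplexPartition:
    """The two-sides split of a complex (e.g. receptor vs ligand chains)."""

    side_a: frozenset[str]
    side_b: frozenset[str]

    def __init__(self, side_a: Iterable[str], side_b: Iterable[str]):
        object.__setattr__(self, "side_a", frozenset(side_a))
        object.__setattr__(self, "side_b", frozenset(side_b))
        if not self.side_a or not self.side_b:
            raise ValueError("both partition sides must be non-empty")
        if self.side_a & self.side_b:
            raise ValueError(f"partition sides overlap: {self.side_a & self.side_b}")

    def side_of(self, chain_id: str) -> str:
        if chain_id in self.side_a:
            return "a"
        if chain_id in self.side_b:
            return "b"
        raise MissingChainError(f"chain {chain_id!r} not in partition")


def infer_element(atom_name: str) -> str:
    """Infer the element symbol from a PDB atom name.

    Follows PDB naming: a leading digit is a position index (e.g. ``1HB``);
    two-letter elements occupy columns 13-14, but for standard amino-acid
    heavy atoms the first alphabetic character is the element.
    """
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    # standard residues contain only C/N/O/S heavy atoms; take first letter
    return stripped[0].upper()


def read_pdb(path: str | Path, pdb_id: str | None = None) -> StructureModel:
    """Parse the first model of a PDB file into a :class:`StructureModel`.

    HETATM records, waters and hydrogens are excluded.  For alternate
    locations only the highest-occupancy conformer is retained (ties broken
    by file order).

    Raises
    ------
    EmptyStructureError
        If no usable ATOM record survives filtering.
    OSError
        If the file cannot be read.
    """
    path = Path(path)
    if pdb_id is None:
        pdb_id = path.stem
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(pdb_id, str(path))
    try:
        model = next(structure.get_models())  # first model only
    except StopIteration:
        raise EmptyStructureError(f"{path}: no model in file")

    chains: dict[str, list[Residue]] = {}
    serial = 0
    for bio_chain in model:
        residues: list[Residue] = []
        for bio_res in bio_chain:
            hetflag, seq_num, icode = bio_res.get_id()
            if hetflag.strip():  # HETATM (includes "W" for waters)
                continue
            if bio_res.get_resname().strip() in _WATER_NAMES:
                continue
            atoms: list[Atom] = []
            for bio_atom in bio_res:
                if bio_atom.is_disordered():
                    # highest occupancy wins; ties -> first listed
                    alts = bio_atom.disordered_get_list()
                    bio_atom = max(alts, key=lambda a: (a.get_occupancy() or 0.0))
                element = (bio_atom.element or "").strip().upper()
                if not element:
                    element = infer_element(bio_atom.get_name())
                if element in ("H", "D"):
                    continue
                serial += 1
                atoms.append(
                    Atom(
                        name=bio_atom.get_name().strip(),
                        element=element,
                        coord=np.array(bio_atom.get_coord(), dtype=float),
                        bfactor=float(bio_atom.get_bfactor() or 0.0),
                        occupancy=float(bio_atom.get_occupancy() or 1.0),
                        altloc=(bio_atom.get_altloc() or "").strip(),
                        serial=serial,
                    )
                )
            if not atoms:
                continue
            aa = bio_res.get_resname().strip().upper()
            if aa not in AA3:
                aa = "UNK"
            residues.append(
                Residue(
                    chain_id=bio_chain.id.strip() or " ",
                    seq_num=int(seq_num),
                    icode=str(icode).strip(),
                    aa_type=aa,
                    atoms=atoms,
                )
            )
        if residues:
            chains[bio_chain.id.strip() or " "] = residues
    if not chains:
        raise EmptyStructureError(f"{path}: no ATOM records after filtering")
    return StructureModel(pdb_id=pdb_id, chains=chains)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as fixed-column ATOM records (one chain block each)."""
    lines: list[str] = []
    serial = 0
    for cid, residues in model.chains.items():
        for res in residues:
            for atom in res.atoms:
                serial += 1
                name = atom.name
                # PDB alignment: 4-char names start at col 13, shorter at 14
                name_field = name if len(name) >= 4 else f" {name:<3s}"
                x, y, z = atom.coord
                lines.append(
                    f"ATOM  {serial:5d} {name_field}{'':1s}{res.aa_type:>3s} "
                    f"{cid[:1]}{res.seq_num:4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}"
                    f"{atom.bfactor:6.2f}          {atom.element:>2s}"
                )
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def partition(
    model: StructureModel, p: ComplexPartition
) -> tuple[StructureModel, StructureModel, StructureModel]:
    """Split a complex into (unbound_a, unbound_b, bound) sub-models.

    Coordinates are untouched: the unbound state is the bound conformation
    of one side viewed in isolation.
    """
    for cid in sorted(p.side_a | p.side_b):
        if cid not in model.chains:
            raise MissingChainError(
                f"partition chain {cid!r} absent from model {model.pdb_id}"
            )
    unbound_a = model.subset([c for c in model.chains if c in p.side_a])
    unbound_b = model.subset([c for c in model.chains if c in p.side_b])
    bound = model.subset([c for c in model.chains if c in (p.side_a | p.side_b)])
    return unbound_a, unbound_b, bound


def classify_atom(residue_aa: str, atom_name: str) -> tuple[str, str]:
    """Classify a heavy atom as (backbone|side_chain, polar|non_polar|other).

    N, CA, C, O (and terminal OXT) are backbone; everything else side chain.
    Polarity follows the element: O/N polar, C non-polar, anything else
    (sulfur included) counts in neither polar nor non-polar sums.
    """
    name = atom_name.strip().upper()
    chain_part = "backbone" if name in _BACKBONE_NAMES else "side_chain"
    element = infer_element(name)
    if element in ("O", "N"):
        polarity = "polar"
    elif element == "C":
        polarity = "non_polar"
    else:
        polarity = "other"
    return chain_part, polarity
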
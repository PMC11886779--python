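"""Core domain records shared across the package.

The central objects are a protein with an explicit all-atom structure
(:class:`ProteinRecord`), a drug given by its SMILES string
(:class:`DrugRecord`), a labelled drug-protein pair, and the pocket /
subpocket hierarchy produced by a cavity-detection tool: pockets carry a
ligandability score ``c_i`` and are decomposed into subpockets whose atoms
line the cavity.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coords: tuple[float, float, float]


@dataclass
class Residue:
    index: int          # PDB residue number, 1-based, canonical key
    name: str           # three-letter residue name
    atoms: list[Atom]

    @property
    def one_letter(self) -> str:
        return AA3_TO_1.get(self.name, "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class ProteinRecord:
    id: str
    sequence: str
    structure: list[Residue] = field(default_factory=list)

    def validate(self) -> None:
        if self.structure:
            if self.sequence and len(self.sequence) != len(self.structure):
                raise ValueError(
                    f"{self.id}: sequence length {len(self.sequence)} != "
                    f"{len(self.structure)} residues")
            indices = [r.index for r in self.structure]
            if any(b <= a for a, b in zip(indices, indices[1:])):
                raise ValueError(f"{self.id}: residue indices not strictly increasing")
            for r in self.structure:
                for a in r.atoms:
                    if not all(np.isfinite(a.coords)):
                        raise ValueError(f"{self.id}: non-finite coordinates at residue {r.index}")

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.structure)

    def residue_by_index(self, index: int) -> Residue:
        for r in self.structure:
            if r.index == index:
                return r
        raise KeyError(f"{self.id}: no residue with index {index}")

    def coords(self) -> np.ndarray:
        return np.array([a.coords for r in self.structure for a in r.atoms], dtype=float)


@dataclass(frozen=True)
class DrugRecord:
    id: str
    smiles: str


@dataclass(frozen=True)
class InteractionPair:
    drug_id: str
    protein_id: str
    label: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


# atom identifier inside a protein structure: (residue index, atom name)
AtomId = tuple[int, str]


@dataclass
class SubpocketEntry:
    subpocket_id: str
    atoms: list[AtomId]


@dataclass
class PocketEntry:
    pocket_id: str
    score: float
    subpockets: list[SubpocketEntry]


@dataclass
class PocketAssignmentFile:
    protein_id: str
    pockets: list[PocketEntry]
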
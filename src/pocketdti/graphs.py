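"""Residue-level protein graphs and atom-level drug graphs.

Protein residues become nodes joined by three edge types — peptide bonds
(chain neighbours), backbone hydrogen bonds (N-O distance below a cutoff,
sequence separation >= 3) and k-nearest-neighbour contacts on C-alpha
distances (k = 5 by default).  Node features concatenate the language-model
embedding row with a small electrostatics-bearing property vector (formal
charge at pH 7, isoelectric point, Kyte-Doolittle hydropathy).

Drug heavy atoms become nodes joined by the parsed SMILES bonds; features
concatenate the language-model row with chemical atom properties.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .types import DrugRecord, ProteinRecord

logger = logging.getLogger(__name__)

EDGE_PEPTIDE, EDGE_HBOND, EDGE_KNN = 0, 1, 2
EDGE_COVALENT, EDGE_CONTACT = 0, 1  # atom-graph edge types (pockets module)


@dataclass
class MolecularGraph:
    """Undirected graph with per-node feature rows and typed edges.

    ``edges`` holds each undirected edge once as (i, j) with i < j;
    ``edge_types`` is a parallel integer array.
    """
    node_features: np.ndarray
    edges: np.ndarray
    edge_types: np.ndarray = field(default=None)
    is_placeholder: bool = False

    def __post_init__(self):
        self.node_features = np.asarray(self.node_features, dtype=np.float32)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.edge_types is None:
            self.edge_types = np.zeros(len(self.edges), dtype=np.int64)
        self.edge_types = np.asarray(self.edge_types, dtype=np.int64)
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-loops are not allowed")

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.node_features.shape[1]

    def unique_edges(self) -> np.ndarray:
        """Undirected edge set with duplicates across types collapsed."""
        if len(self.edges) == 0:
            return self.edges
        canon = np.sort(self.edges, axis=1)
        return np.unique(canon, axis=0)


def _dedupe_typed(pairs: list[tuple[int, int, int]]) -> tuple[np.ndarray, np.ndarray]:
    seen = {}
    for i, j, t in pairs:
        a, b = (i, j) if i < j else (j, i)
        if (a, b, t) not in seen:
            seen[(a, b, t)] = None
    if not seen:
        return np.zeros((0, 2), dtype=np.int64), np.zeros(0, dtype=np.int64)
    arr = np.array(sorted(seen), dtype=np.int64)
    return arr[:, :2], arr[:, 2]


# ---------------------------------------------------------------------------
# residue properties
# ---------------------------------------------------------------------------

# columns: formal charge at pH 7, isoelectric point, Kyte-Doolittle hydropathy
RESIDUE_PROPERTY_TABLE: dict[str, tuple[float, float, float]] = {
    "A": (0.0, 6.00, 1.8),  "R": (1.0, 10.76, -4.5), "N": (0.0, 5.41, -3.5),
    "D": (-1.0, 2.77, -3.5), "C": (0.0, 5.07, 2.5),  "Q": (0.0, 5.65, -3.5),
    "E": (-1.0, 3.22, -3.5), "G": (0.0, 5.97, -0.4), "H": (0.1, 7.59, -3.2),
    "I": (0.0, 6.02, 4.5),  "L": (0.0, 5.98, 3.8),  "K": (1.0, 9.74, -3.9),
    "M": (0.0, 5.74, 1.9),  "F": (0.0, 5.48, 2.8),  "P": (0.0, 6.30, -1.6),
    "S": (0.0, 5.68, -0.8), "T": (0.0, 5.60, -0.7), "W": (0.0, 5.89, -0.9),
    "Y": (0.0, 5.66, -1.3), "V": (0.0, 5.96, 4.2),
}
P_PROTEIN = 3

_MEAN_ROW = tuple(np.mean([v for v in RESIDUE_PROPERTY_TABLE.values()], axis=0))


def residue_properties(sequence: str) -> np.ndarray:
    """Per-residue property rows, shape (N, 3); unknown 'X' gets the mean row."""
    rows = [RESIDUE_PROPERTY_TABLE.get(aa, _MEAN_ROW) for aa in sequence]
    return np.asarray(rows, dtype=np.float32)


# ---------------------------------------------------------------------------
# drug atom properties
# ---------------------------------------------------------------------------

_ELEMENTS = ["C", "N", "O", "S", "P", "F", "Cl", "Br", "I"]
P_DRUG = len(_ELEMENTS) + 1 + 4  # one-hot (+other), degree, charge, aromatic, implicit H


def atom_properties(mol: Chem.Mol) -> np.ndarray:
    """Per-heavy-atom chemical property rows, shape (N, P_DRUG)."""
    rows = np.zeros((mol.GetNumAtoms(), P_DRUG), dtype=np.float32)
    for i, atom in enumerate(mol.GetAtoms()):
        sym = atom.GetSymbol()
        rows[i, _ELEMENTS.index(sym) if sym in _ELEMENTS else len(_ELEMENTS)] = 1.0
        rows[i, len(_ELEMENTS) + 1] = atom.GetDegree()
        rows[i, len(_ELEMENTS) + 2] = atom.GetFormalCharge()
        rows[i, len(_ELEMENTS) + 3] = float(atom.GetIsAromatic())
        rows[i, len(_ELEMENTS) + 4] = atom.GetNumImplicitHs()
    return rows


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

# fixed standardization constants: residue columns use the 20-row property
# table's statistics; drug atom columns use nominal scales for counts/flags
_RES_PROP_STATS = (np.mean(list(RESIDUE_PROPERTY_TABLE.values()), axis=0),
                   np.std(list(RESIDUE_PROPERTY_TABLE.values()), axis=0))


def _balanced_concat(embeddings: np.ndarray, properties: np.ndarray,
                     stats: tuple[np.ndarray, np.ndarray] | None) -> np.ndarray:
    """Concatenate the LM block with standardized, magnitude-balanced properties.

    Without balancing, a handful of property columns is negligible next to a
    ~unit-variance block of >1000 LM dimensions, and the first GCN layer
    starts essentially blind to them.  Properties are z-scored with *fixed*
    constants (identical for every entity) and the block is rescaled so both
    groups carry comparable total energy.
    """
    if stats is not None:
        mu, sd = (np.asarray(s, dtype=np.float32) for s in stats)
        properties = (properties - mu) / np.where(sd < 1e-6, 1.0, sd)
    gain = np.sqrt(embeddings.shape[1] / properties.shape[1])
    return np.concatenate([embeddings, gain * properties], axis=1).astype(np.float32)


def _ca_coords(protein: ProteinRecord) -> np.ndarray:
    coords = np.zeros((len(protein.structure), 3))
    for i, res in enumerate(protein.structure):
        ca = res.atom("CA")
        if ca is None:
            logger.warning("%s: residue %d lacks CA; using centroid", protein.id, res.index)
            coords[i] = np.mean([a.coords for a in res.atoms], axis=0)
        else:
            coords[i] = ca.coords
    return coords


def build_residue_graph(protein: ProteinRecord, embeddings: np.ndarray,
                        properties: np.ndarray | None = None, k: int = 5,
                        hbond_cutoff: float = 3.5) -> MolecularGraph:
    """Protein residue graph with peptide, hydrogen-bond and KNN edges."""
    n = len(protein.structure)
    if embeddings.shape[0] != n:
        raise ValueError(f"{protein.id}: {embeddings.shape[0]} embedding rows for {n} residues")
    if properties is None:
        properties = residue_properties(protein.sequence)
    pairs: list[tuple[int, int, int]] = [(i, i + 1, EDGE_PEPTIDE) for i in range(n - 1)]

    n_xyz = np.full((n, 3), np.nan)
    o_xyz = np.full((n, 3), np.nan)
    for i, res in enumerate(protein.structure):
        if (a := res.atom("N")) is not None:
            n_xyz[i] = a.coords
        if (a := res.atom("O")) is not None:
            o_xyz[i] = a.coords
    for i in range(n):
        for j in range(n):
            if abs(i - j) < 3 or np.isnan(n_xyz[i]).any() or np.isnan(o_xyz[j]).any():
                continue
            if np.linalg.norm(n_xyz[i] - o_xyz[j]) < hbond_cutoff:
                pairs.append((i, j, EDGE_HBOND))

    ca = _ca_coords(protein)
    dist = np.linalg.norm(ca[:, None] - ca[None, :], axis=-1)
    for i in range(n):
        # ties broken by lower residue position (stable argsort on (distance, j))
        order = sorted((j for j in range(n) if j != i), key=lambda j: (dist[i, j], j))
        for j in order[:k]:
            pairs.append((i, j, EDGE_KNN))

    edges, types = _dedupe_typed(pairs)
    features = _balanced_concat(embeddings, properties, _RES_PROP_STATS)
    return MolecularGraph(features, edges, types)


def build_drug_graph(drug: DrugRecord, embeddings: np.ndarray,
                     properties: np.ndarray | None = None) -> MolecularGraph:
    """Drug heavy-atom graph; edges are the parsed SMILES bonds."""
    mol = Chem.MolFromSmiles(drug.smiles)
    if mol is None:
        raise ValueError(f"{drug.id}: unparsable SMILES {drug.smiles!r}")
    if embeddings.shape[0] != mol.GetNumAtoms():
        raise ValueError(f"{drug.id}: {embeddings.shape[0]} embedding rows for "
                         f"{mol.GetNumAtoms()} heavy atoms")
    if properties is None:
        properties = atom_properties(mol)
    pairs = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), 0) for b in mol.GetBonds()]
    edges, types = _dedupe_typed(pairs)
    features = _balanced_concat(embeddings, properties, None)
    return MolecularGraph(features, edges, types)
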
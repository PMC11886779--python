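"""End-to-end model: entity featurization plus the full forward pass.

``featurize`` turns raw records (SMILES, sequences + structures, pocket
assignments) into reusable per-entity inputs: a residue graph and an
M-slot subpocket graph set per protein, an atom graph per drug.
``DTIModel`` encodes a batch of pairs with the three GCN encoders, runs the
rank-aware transformer over the (M+2)-token matrix and returns interaction
probabilities.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import embeddings as emb
from .encoders import GcnConfig, GraphEncoder
from .graphs import (MolecularGraph, P_DRUG, P_PROTEIN, build_drug_graph,
                     build_residue_graph, residue_properties)
from .interaction import (InteractionInput, PredictionHead, TransformerConfig,
                          TransformerEncoder, assemble_input)
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import Module
from .pockets import (DEFAULT_M, POCKET_ATOM_DIM, Pocket, SubpocketSet,
                      detect_pockets_geometric, pockets_from_assignment,
                      subpocket_set_graphs)
from .types import DrugRecord, InteractionPair, PocketAssignmentFile, ProteinRecord

logger = logging.getLogger(__name__)

PROTEIN_IN_DIM = emb.PROTEIN_DIM + P_PROTEIN
DRUG_IN_DIM = emb.DRUG_DIM + P_DRUG


@dataclass
class ModelConfig:
    d: int = 128
    gcn_layers: int = 3
    dropout: float = 0.1
    M: int = DEFAULT_M
    heads: int = 4
    ff_dim: int = 512
    tx_layers: int = 1
    knn_k: int = 5

    def transformer(self) -> TransformerConfig:
        return TransformerConfig(d=self.d, heads=self.heads, ff_dim=self.ff_dim,
                                 dropout=self.dropout, layers=self.tx_layers,
                                 max_rank=self.M)


@dataclass
class ProteinInputs:
    residue_graph: MolecularGraph
    subpocket_set: SubpocketSet
    subpocket_graphs: list[MolecularGraph]   # length M, placeholders last

    @property
    def ranks(self) -> np.ndarray:
        return np.asarray(self.subpocket_set.ranks, dtype=np.int64)


@dataclass
class FeaturizedDataset:
    proteins: dict[str, ProteinInputs]
    drugs: dict[str, MolecularGraph]
    M: int


def featurize_protein(protein: ProteinRecord, pockets: list[Pocket],
                      provider: emb.EmbeddingProvider, M: int = DEFAULT_M,
                      knn_k: int = 5) -> ProteinInputs:
    matrix = emb.embed_protein(protein.sequence, provider)
    graph = build_residue_graph(protein, matrix, residue_properties(protein.sequence), k=knn_k)
    subset, sub_graphs = subpocket_set_graphs(pockets, protein, M=M)
    return ProteinInputs(graph, subset, sub_graphs)


def featurize_drug(drug: DrugRecord, provider: emb.EmbeddingProvider) -> MolecularGraph:
    matrix, _ = emb.embed_drug(drug.smiles, provider)
    return build_drug_graph(drug, matrix)


def featurize(drugs: list[DrugRecord], proteins: list[ProteinRecord],
              assignments: dict[str, PocketAssignmentFile] | None,
              protein_provider: emb.EmbeddingProvider,
              drug_provider: emb.EmbeddingProvider,
              M: int = DEFAULT_M, knn_k: int = 5) -> FeaturizedDataset:
    """Featurize every entity once.  Proteins without an assignment entry
    fall back to the geometric cavity detector."""
    protein_inputs = {}
    for protein in proteins:
        if assignments is not None and protein.id in assignments:
            pockets = pockets_from_assignment(assignments[protein.id], protein)
        else:
            logger.info("%s: no pocket assignment; using geometric detector", protein.id)
            pockets = detect_pockets_geometric(protein)
        protein_inputs[protein.id] = featurize_protein(protein, pockets,
                                                       protein_provider, M, knn_k)
    drug_graphs = {d.id: featurize_drug(d, drug_provider) for d in drugs}
    return FeaturizedDataset(protein_inputs, drug_graphs, M)


class DTIModel(Module):
    """Drug/protein/subpocket encoders + rank-aware transformer + head."""

    def __init__(self, config: ModelConfig = ModelConfig(), seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.drug_encoder = GraphEncoder(
            GcnConfig(DRUG_IN_DIM, config.d, config.gcn_layers, config.dropout), rng)
        self.protein_encoder = GraphEncoder(
            GcnConfig(PROTEIN_IN_DIM, config.d, config.gcn_layers, config.dropout), rng)
        self.subpocket_encoder = GraphEncoder(
            GcnConfig(POCKET_ATOM_DIM, config.d, config.gcn_layers, config.dropout), rng)
        self.transformer = TransformerEncoder(config.transformer(), rng)
        self.head = PredictionHead(config.d, rng)

    @staticmethod
    def _encode_unique(encoder: GraphEncoder, graphs, training, rng):
        """Encode each distinct graph object once, then gather per slot.

        Entities recur across pairs in a batch and placeholder slots all
        point at one shared graph, so this cuts redundant encoder work
        without changing the result (weight sharing makes identical graphs
        yield identical rows).
        """
        unique: dict[int, int] = {}
        unique_graphs = []
        index = np.empty(len(graphs), dtype=np.int64)
        for slot, g in enumerate(graphs):
            key = id(g)
            if key not in unique:
                unique[key] = len(unique_graphs)
                unique_graphs.append(g)
            index[slot] = unique[key]
        encoded = encoder.encode(unique_graphs, training, rng)
        if len(unique_graphs) == len(graphs):
            return encoded
        return ag.gather_rows(encoded, index)

    def interaction_input(self, pairs: list[InteractionPair], data: FeaturizedDataset,
                          training: bool = False,
                          rng: np.random.Generator | None = None) -> InteractionInput:
        drug_graphs = [data.drugs[p.drug_id] for p in pairs]
        prot_inputs = [data.proteins[p.protein_id] for p in pairs]
        b, m, d = len(pairs), data.M, self.config.d
        drug_vecs = self._encode_unique(self.drug_encoder, drug_graphs, training, rng)
        prot_vecs = self._encode_unique(
            self.protein_encoder, [pi.residue_graph for pi in prot_inputs], training, rng)
        flat_graphs = [g for pi in prot_inputs for g in pi.subpocket_graphs]
        sub_vecs = self._encode_unique(self.subpocket_encoder, flat_graphs,
                                       training, rng).reshape(b, m, d)
        ranks = np.stack([pi.ranks for pi in prot_inputs])
        return assemble_input(drug_vecs, prot_vecs, sub_vecs, ranks)

    def forward(self, pairs: list[InteractionPair], data: FeaturizedDataset,
                training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Interaction probabilities for a batch of pairs, shape (B,)."""
        inp = self.interaction_input(pairs, data, training, rng)
        updated = self.transformer(inp, training, rng)
        return self.head(updated)

    def predict(self, pairs: list[InteractionPair], data: FeaturizedDataset,
                batch_size: int = 64) -> np.ndarray:
        """Inference-mode probabilities (no dropout), minibatched."""
        out = []
        for i in range(0, len(pairs), batch_size):
            out.append(self.forward(pairs[i:i + batch_size], data).data)
        return np.concatenate(out) if out else np.zeros(0, dtype=np.float32)

    @property
    def attention_tensors(self) -> list[np.ndarray]:
        return self.transformer.attention_tensors

    def save(self, path) -> None:
        import dataclasses
        import json
        from pathlib import Path
        path = Path(path)
        np.savez(path, **self.state_dict())
        path.with_suffix(".config.json").write_text(
            json.dumps(dataclasses.asdict(self.config)))

    @classmethod
    def load(cls, path) -> "DTIModel":
        import json
        from pathlib import Path
        path = Path(path)
        cfg = ModelConfig(**json.loads(path.with_suffix(".config.json").read_text()))
        model = cls(cfg)
        model.load_state_dict(dict(np.load(path)))
        return model
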
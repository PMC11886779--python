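"""GCN graph encoders with max + attention-gated weighted pooling.

Three encoder instances with distinct parameters are used by the full
model: one for the protein residue graph, one for the drug atom graph, and
one shared across all M subpocket graphs (weight sharing across the set is
what makes the M x d subpocket embedding matrix consistent).

Propagation is the standard graph convolution: symmetric-normalised
adjacency with self-loops, per-layer linear map and ReLU.  Pooling
concatenates the elementwise max over nodes with a softmax-gated weighted
sum, then projects linearly to the model width d.  Variable-size graphs are
encoded together through one block-diagonal sparse adjacency and segment
reductions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graphs import MolecularGraph
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import Linear, Module


@dataclass
class GcnConfig:
    in_dim: int
    d: int = 128            # pooled output width
    layers: int = 3
    dropout: float = 0.1

    def widths(self) -> list[int]:
        return [self.in_dim] + [self.d] * self.layers


def normalized_adjacency(graph: MolecularGraph) -> sp.csr_matrix:
    """D^{-1/2} (A + I) D^{-1/2} over the union of the graph's edge types.

    Cached on the graph object: topology is fixed after construction.
    """
    cached = getattr(graph, "_norm_adj", None)
    if cached is not None:
        return cached
    n = graph.n_nodes
    edges = graph.unique_edges()
    rows = np.concatenate([edges[:, 0], edges[:, 1], np.arange(n)])
    cols = np.concatenate([edges[:, 1], edges[:, 0], np.arange(n)])
    a = sp.coo_matrix((np.ones(len(rows), dtype=np.float32), (rows, cols)), shape=(n, n))
    deg = np.asarray(a.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    norm = a.multiply(d_inv_sqrt[:, None]).multiply(d_inv_sqrt[None, :]).tocsr()
    object.__setattr__(graph, "_norm_adj", norm)
    return norm


@dataclass
class GraphBatch:
    """Several graphs packed into one node matrix + block-diagonal adjacency."""
    features: np.ndarray
    adjacency: sp.csr_matrix
    segments: np.ndarray      # node -> graph slot
    n_graphs: int

    @classmethod
    def from_graphs(cls, graphs: list[MolecularGraph]) -> "GraphBatch":
        if not graphs:
            raise ValueError("empty graph batch")
        feats = np.concatenate([g.node_features for g in graphs], axis=0)
        adj = sp.block_diag([normalized_adjacency(g) for g in graphs], format="csr")
        segments = np.concatenate([np.full(g.n_nodes, i) for i, g in enumerate(graphs)])
        return cls(feats.astype(np.float32), adj, segments, len(graphs))


class GraphEncoder(Module):
    """GCN stack + (max || gated-weighted) pooling -> d-dimensional summary."""

    def __init__(self, config: GcnConfig, rng: np.random.Generator):
        self.config = config
        widths = config.widths()
        self.gcn_layers = [Linear(a, b, rng) for a, b in zip(widths[:-1], widths[1:])]
        self.gate = Linear(config.d, 1, rng)
        self.project = Linear(2 * config.d, config.d, rng)

    # -- node-level forward -------------------------------------------------
    def node_representations(self, batch: GraphBatch, training: bool = False,
                             rng: np.random.Generator | None = None) -> Tensor:
        h = Tensor(batch.features)
        for i, layer in enumerate(self.gcn_layers):
            h = ag.sparse_matmul(batch.adjacency, h)
            h = layer(h)
            h = ag.relu(h)
            if i < len(self.gcn_layers) - 1:
                h = ag.dropout(h, self.config.dropout, rng, training)
        return h

    # -- pooling -------------------------------------------------------------
    def pool(self, h: Tensor, batch: GraphBatch) -> Tensor:
        seg, n = batch.segments, batch.n_graphs
        max_pool = ag.segment_max(h, seg, n)
        scores = self.gate(h)                                # (nodes, 1)
        m = ag.segment_max(scores, seg, n)
        e = ag.exp(scores - ag.gather_rows(m, seg))
        z = ag.gather_rows(ag.segment_sum(e, seg, n), seg)
        weights = e / z                                       # softmax within graph
        weighted = ag.segment_sum(h * weights, seg, n)
        return self.project(ag.concat([max_pool, weighted], axis=-1))

    def encode(self, graphs: list[MolecularGraph], training: bool = False,
               rng: np.random.Generator | None = None) -> Tensor:
        """Pooled d-dimensional embedding per graph, shape (len(graphs), d)."""
        batch = GraphBatch.from_graphs(graphs)
        h = self.node_representations(batch, training, rng)
        return self.pool(h, batch)


def gcn_forward(graph: MolecularGraph, encoder: GraphEncoder,
                training: bool = False) -> Tensor:
    """Node representation matrix of a single graph (rows = nodes)."""
    return encoder.node_representations(GraphBatch.from_graphs([graph]), training)


def encode_subpocket_set(encoder: GraphEncoder, graphs: list[MolecularGraph],
                         M: int, training: bool = False,
                         rng: np.random.Generator | None = None) -> Tensor:
    """Shared-weight encoding of exactly M subpocket graphs -> (M, d)."""
    if len(graphs) != M:
        raise ValueError(f"expected exactly {M} subpocket graphs, got {len(graphs)}")
    return encoder.encode(graphs, training, rng)
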
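"""Rank-aware transformer interaction head.

The (M+2) x d token matrix X stacks the pooled drug embedding (row 0), the
pooled protein embedding (row 1) and the M subpocket rows.  Each subpocket
token is positionally encoded by its parent pocket's rank k_i through a
learned, zero-initialised embedding table; the two global tokens and all
placeholder slots carry position 0.  Multi-head self-attention updates X,
the drug and protein rows of the result are concatenated into O in R^{2d},
and a ReLU MLP followed by a linear unit produces the interaction logit o
with P = sigmoid(o).  Training minimises binary cross-entropy
L = -[Y log P + (1-Y) log(1-P)].
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import MLP, EmbeddingTable, LayerNorm, Linear, Module

BCE_EPS = 1e-7


@dataclass
class TransformerConfig:
    d: int = 128
    heads: int = 4
    ff_dim: int = 512
    dropout: float = 0.1
    layers: int = 1
    max_rank: int = 64      # positional table covers ranks 0..max_rank
    qk_init_gain: float = 5.0  # widens initial attention logits; see methods note

    def __post_init__(self):
        if self.d % self.heads:
            raise ValueError(f"model width {self.d} not divisible by {self.heads} heads")


@dataclass
class InteractionInput:
    """Batched token matrix plus integer positions, roles [drug, protein, s_1..s_M]."""
    X: Tensor                 # (B, M+2, d)
    positions: np.ndarray     # (B, M+2) int


def assemble_input(drug: Tensor, protein: Tensor, subpockets: Tensor,
                   ranks: np.ndarray) -> InteractionInput:
    """Stack [drug, protein, s_1..s_M] rows and their positional indices.

    Accepts single samples ((d,), (M, d), ranks (M,)) or batches with a
    leading batch axis.  Positions are 0 for the two global rows and for
    placeholder slots, k_i for real subpockets.
    """
    single = drug.ndim == 1
    if single:
        drug, protein = drug.reshape(1, -1), protein.reshape(1, -1)
        subpockets = subpockets.reshape(1, *subpockets.shape)
        ranks = np.asarray(ranks)[None, :]
    b, m, d = subpockets.shape
    if drug.shape != (b, d) or protein.shape != (b, d):
        raise ValueError(f"width mismatch: drug {drug.shape}, protein {protein.shape}, "
                         f"subpockets {subpockets.shape}")
    ranks = np.asarray(ranks, dtype=np.int64).reshape(b, m)
    x = ag.concat([drug.reshape(b, 1, d), protein.reshape(b, 1, d), subpockets], axis=1)
    positions = np.concatenate([np.zeros((b, 2), dtype=np.int64), ranks], axis=1)
    return InteractionInput(x, positions)


class PositionalEncoding(Module):
    """Learned embedding per integer pocket rank, zero-initialised so the
    encoding starts as the identity and training decides its geometry."""

    def __init__(self, config: TransformerConfig):
        self.table = EmbeddingTable(config.max_rank + 1, config.d, zero_init=True)

    def __call__(self, inp: InteractionInput) -> Tensor:
        return inp.X + self.table(inp.positions)


class TransformerLayer(Module):
    """Post-norm transformer encoder layer; attention weights retained."""

    def __init__(self, config: TransformerConfig, rng: np.random.Generator):
        d = config.d
        self.config = config
        self.wq, self.wk, self.wv = (Linear(d, d, rng) for _ in range(3))
        # glorot-width logits collapse to a near-uniform softmax at this d;
        # a larger query/key scale keeps early attention non-degenerate
        self.wq.weight.data *= config.qk_init_gain
        self.wk.weight.data *= config.qk_init_gain
        self.wo = Linear(d, d, rng)
        self.ff1 = Linear(d, config.ff_dim, rng)
        self.ff2 = Linear(config.ff_dim, d, rng)
        self.norm1, self.norm2 = LayerNorm(d), LayerNorm(d)
        self.attention: np.ndarray | None = None  # (B, heads, T, T) from last call

    def _heads(self, x: Tensor, b: int, t: int) -> Tensor:
        h, dh = self.config.heads, self.config.d // self.config.heads
        return x.reshape(b, t, h, dh).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        b, t, d = x.shape
        h, dh = self.config.heads, d // self.config.heads
        q, k, v = self._heads(self.wq(x), b, t), self._heads(self.wk(x), b, t), \
            self._heads(self.wv(x), b, t)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        att = ag.softmax(scores, axis=-1)                    # (B, h, T, T)
        self.attention = att.data.copy()
        ctx = (att @ v).transpose(0, 2, 1, 3).reshape(b, t, d)
        x = self.norm1(x + ag.dropout(self.wo(ctx), self.config.dropout, rng, training))
        ff = self.ff2(ag.relu(self.ff1(x)))
        return self.norm2(x + ag.dropout(ff, self.config.dropout, rng, training))


class TransformerEncoder(Module):
    def __init__(self, config: TransformerConfig, rng: np.random.Generator):
        self.config = config
        self.positional = PositionalEncoding(config)
        self.layers = [TransformerLayer(config, rng) for _ in range(config.layers)]

    def __call__(self, inp: InteractionInput, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        x = self.positional(inp)
        for layer in self.layers:
            x = layer(x, training, rng)
        return x

    @property
    def attention_tensors(self) -> list[np.ndarray]:
        """Per-layer attention from the most recent forward pass."""
        return [layer.attention for layer in self.layers if layer.attention is not None]


class PredictionHead(Module):
    """O = [drug row || protein row] -> MLP -> linear logit -> sigmoid."""

    def __init__(self, d: int, rng: np.random.Generator,
                 mlp_widths: tuple[int, ...] | None = None):
        widths = list(mlp_widths) if mlp_widths else [2 * d, d, d // 2]
        self.mlp = MLP(widths, rng)
        self.out = Linear(widths[-1], 1, rng)

    def logit(self, x_updated: Tensor) -> Tensor:
        o_embed = ag.concat([x_updated[:, 0, :], x_updated[:, 1, :]], axis=-1)  # (B, 2d)
        return self.out(self.mlp(o_embed)).reshape(-1)

    def __call__(self, x_updated: Tensor) -> Tensor:
        return ag.sigmoid(self.logit(x_updated))


def bce_loss(labels: np.ndarray, probabilities: Tensor) -> Tensor:
    """Mean binary cross-entropy with probabilities clipped to [eps, 1-eps]."""
    y = np.asarray(labels, dtype=np.float32).reshape(-1)
    p = ag.clip(probabilities.reshape(-1), BCE_EPS, 1.0 - BCE_EPS)
    losses = -(Tensor(y) * ag.log(p) + Tensor(1.0 - y) * ag.log(1.0 - p))
    return losses.mean()
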
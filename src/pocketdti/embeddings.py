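"""Pluggable per-residue / per-atom language-model embeddings.

The architecture consumes 1280-d per-residue vectors for proteins and 384-d
per-token vectors for drug SMILES, reduced to one row per heavy atom.  Any
object satisfying :class:`EmbeddingProvider` can supply them; the package
ships :class:`StubProvider`, a deterministic content-hashed pseudo-random
provider that exercises every shape contract without model downloads.
"""
from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
from rdkit import Chem

logger = logging.getLogger(__name__)

PROTEIN_DIM = 1280
DRUG_DIM = 384
VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")


class AlignmentError(ValueError):
    pass


class EmbeddingProvider(Protocol):
    dim: int
    context_limit: int | None

    def embed_tokens(self, tokens: Sequence[str]) -> np.ndarray: ...


class StubProvider:
    """Deterministic pseudo-random token embeddings.

    Row ``t`` is a unit-variance standard-normal vector whose generator seed
    is a hash of ``(seed, token string, t)``; identical inputs therefore give
    bit-identical matrices on any platform, and changing one token changes
    exactly that row.
    """

    context_limit: int | None = None

    def __init__(self, dim: int, seed: int = 0):
        if dim < 1:
            raise ValueError("dim must be >= 1")
        self.dim = dim
        self.seed = seed
        self.calls = 0

    def _row(self, token: str, position: int) -> np.ndarray:
        key = f"{self.seed}|{token}|{position}".encode()
        digest = hashlib.blake2b(key, digest_size=8).digest()
        rng = np.random.Generator(np.random.PCG64(int.from_bytes(digest, "little")))
        return rng.standard_normal(self.dim)

    def embed_tokens(self, tokens: Sequence[str]) -> np.ndarray:
        self.calls += 1
        return np.stack([self._row(tok, t) for t, tok in enumerate(tokens)]).astype(np.float32)


def stub_provider(dim: int, seed: int = 0) -> StubProvider:
    return StubProvider(dim, seed)


# ---------------------------------------------------------------------------
# proteins
# ---------------------------------------------------------------------------

def embed_protein(sequence: str, provider: EmbeddingProvider) -> np.ndarray:
    """Per-residue embedding matrix, shape (len(sequence), provider.dim).

    Sequences beyond the provider's context limit are embedded in
    overlapping windows (overlap 64) and stitched from window centres.
    """
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - VALID_AA
    if bad:
        raise ValueError(f"invalid residues {sorted(bad)} in sequence")
    tokens = list(sequence)
    limit = getattr(provider, "context_limit", None)
    if limit is None or len(tokens) <= limit:
        out = provider.embed_tokens(tokens)
    else:
        logger.info("sequence length %d exceeds provider context %d; windowing", len(tokens), limit)
        out = _windowed_embed(tokens, provider, limit, overlap=64)
    if out.shape != (len(sequence), provider.dim):
        raise ValueError(f"provider returned {out.shape}, expected {(len(sequence), provider.dim)}")
    if not np.all(np.isfinite(out)):
        raise ValueError("provider returned non-finite values")
    return out


def _windowed_embed(tokens: list[str], provider: EmbeddingProvider,
                    limit: int, overlap: int) -> np.ndarray:
    step = limit - overlap
    rows = np.zeros((len(tokens), provider.dim), dtype=np.float32)
    filled = np.zeros(len(tokens), dtype=bool)
    start = 0
    while start < len(tokens):
        stop = min(start + limit, len(tokens))
        window = provider.embed_tokens(tokens[start:stop])
        lo = start if start == 0 else start + overlap // 2
        hi = stop if stop == len(tokens) else stop - overlap // 2
        keep = ~filled[lo:hi]
        rows[lo:hi][keep] = window[lo - start:hi - start][keep]
        filled[lo:hi] |= True
        if stop == len(tokens):
            break
        start += step
    return rows


# ---------------------------------------------------------------------------
# drugs: SMILES tokenization and token -> atom alignment
# ---------------------------------------------------------------------------

_SMILES_TOKEN = re.compile(
    r"(\[[^\]]+\]|Br|Cl|B|C|N|O|S|P|F|I|b|c|n|o|s|p|\(|\)|\.|=|#|\-|\+|\\|/|:|~|@|\?|>|\*|\$|%\d{2}|\d)")

_ATOM_TOKENS = {"B", "Br", "C", "Cl", "N", "O", "S", "P", "F", "I",
                "b", "c", "n", "o", "s", "p", "*"}


def tokenize_smiles(smiles: str) -> list[str]:
    tokens = _SMILES_TOKEN.findall(smiles)
    if "".join(tokens) != smiles:
        raise ValueError(f"SMILES {smiles!r} contains untokenizable characters")
    return tokens


def is_atom_token(token: str) -> bool:
    return token.startswith("[") or token in _ATOM_TOKENS


@dataclass
class TokenAtomAlignment:
    """Order-preserving pairing of atom-bearing SMILES tokens with atoms."""
    mapping: list[tuple[int, int]]             # (token index, atom index)
    unmatched: list[int] = field(default_factory=list)  # non-atom token indices


def align_tokens_to_atoms(smiles: str, tokens: Sequence[str]) -> TokenAtomAlignment:
    """Pair atom-bearing tokens with SMILES atom order by a left-to-right scan.

    Ring digits, bond symbols, branches and special tokens are reported as
    unmatched.  The number of atom-bearing tokens must equal the molecule's
    heavy-atom count, otherwise an :class:`AlignmentError` carries both.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES {smiles!r}")
    n_atoms = mol.GetNumAtoms()
    mapping, unmatched = [], []
    atom_idx = 0
    for t, tok in enumerate(tokens):
        if is_atom_token(tok):
            mapping.append((t, atom_idx))
            atom_idx += 1
        else:
            unmatched.append(t)
    if atom_idx != n_atoms:
        raise AlignmentError(
            f"{smiles!r}: {atom_idx} atom-bearing tokens vs {n_atoms} parsed heavy atoms")
    return TokenAtomAlignment(mapping, unmatched)


def embed_drug(smiles: str, provider: EmbeddingProvider) -> tuple[np.ndarray, TokenAtomAlignment]:
    """Per-heavy-atom embedding matrix plus the token/atom alignment used."""
    tokens = tokenize_smiles(smiles)
    alignment = align_tokens_to_atoms(smiles, tokens)
    token_matrix = provider.embed_tokens(tokens)
    rows = np.stack([token_matrix[t] for t, _ in alignment.mapping])
    return rows.astype(np.float32), alignment


# ---------------------------------------------------------------------------
# caching
# ---------------------------------------------------------------------------

def _content_key(text: str, provider: EmbeddingProvider) -> str:
    name = type(provider).__name__
    seed = getattr(provider, "seed", "")
    return hashlib.sha256(f"{name}|{provider.dim}|{seed}|{text}".encode()).hexdigest()[:24]


def cache_embeddings(texts: dict[str, str], provider: EmbeddingProvider,
                     cache_dir: str | Path,
                     kind: str = "protein") -> dict[str, Path]:
    """Compute (or load) embeddings for ``{record id: text}``, one .npy per
    distinct content hash; returns id -> file path and writes a JSON index."""
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    index_path = cache_dir / "index.json"
    index = json.loads(index_path.read_text()) if index_path.exists() else {}
    out: dict[str, Path] = {}
    for rec_id, text in texts.items():
        key = _content_key(text, provider)
        fpath = cache_dir / f"{key}.npy"
        cached = None
        if fpath.exists():
            try:
                cached = np.load(fpath)
            except Exception:
                logger.warning("corrupt cache file %s; recomputing", fpath)
        if cached is None:
            matrix = (embed_protein(text, provider) if kind == "protein"
                      else embed_drug(text, provider)[0])
            np.save(fpath, matrix)
        index[rec_id] = fpath.name
        out[rec_id] = fpath
    index_path.write_text(json.dumps(index, indent=1, sort_keys=True))
    return out
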
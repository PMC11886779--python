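"""Attention-based binding-site interpretation.

The transformer's attention over the (M+2) interaction tokens is averaged
over layers, heads and query tokens into the attention *received* by each
key token.  Real subpocket tokens are then ranked by received attention,
and the per-subpocket scores can be projected onto the structure as PDB
B-factors for viewer colouring.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import write_pdb
from .pockets import SubpocketSet
from .types import ProteinRecord


@dataclass
class AttentionSummary:
    """Received attention per token: [drug, protein, s_1..s_M], sums to 1."""
    received: np.ndarray          # (M+2,)
    placeholder_mask: np.ndarray  # (M+2,) bool; True for placeholder slots

    @property
    def drug(self) -> float:
        return float(self.received[0])

    @property
    def protein(self) -> float:
        return float(self.received[1])

    def subpocket_scores(self) -> np.ndarray:
        return self.received[2:]


def summarize_attention(attention_tensors: list[np.ndarray],
                        n_real_subpockets: int | None = None) -> AttentionSummary:
    """Aggregate per-layer attention arrays of shape (..., T, T).

    The mean over layers, heads and query rows of the attention paid to each
    key is renormalised to sum to one.  Leading axes beyond the head axis
    (e.g. a batch axis) must be selected by the caller first.
    """
    if not attention_tensors:
        raise ValueError("no attention tensors supplied")
    t = attention_tensors[0].shape[-1]
    per_layer = [a.reshape(-1, t, t).mean(axis=(0, 1)) for a in attention_tensors]
    received = np.mean(per_layer, axis=0)
    received = received / received.sum()
    mask = np.zeros(t, dtype=bool)
    if n_real_subpockets is not None:
        mask[2 + n_real_subpockets:] = True
    return AttentionSummary(received, mask)


def rank_subpockets(summary: AttentionSummary,
                    subpocket_ids: list[str]) -> list[str]:
    """Real subpocket ids sorted by received attention, descending; ties
    break toward the lower slot index.  Placeholders are excluded."""
    scores = summary.subpocket_scores()
    real = [(i, sid) for i, sid in enumerate(subpocket_ids)
            if not summary.placeholder_mask[2 + i]]
    order = sorted(real, key=lambda item: (-scores[item[0]], item[0]))
    return [sid for _, sid in order]


def project_to_structure(summary: AttentionSummary, subpocket_set: SubpocketSet,
                         protein: ProteinRecord, out_prefix: str | Path) -> dict:
    """Write attention onto the structure: a PDB whose B-factor column holds
    each subpocket's min-max-normalised attention (atoms outside all
    subpockets get 0.00) plus a companion JSON with the ranking."""
    subs = subpocket_set.subpockets
    ids = [s.subpocket_id for s in subs]
    ranking = rank_subpockets(summary, ids)
    scores = summary.subpocket_scores()[:len(subs)]
    if len(scores):
        lo, hi = scores.min(), scores.max()
        normed = (scores - lo) / (hi - lo) if hi > lo else np.ones_like(scores)
    else:
        normed = scores
    bfactors: dict[tuple[int, str], float] = {}
    for sub, val in zip(subs, normed):
        for atom in sub.atoms:
            key = (atom.residue_index, atom.atom_name)
            bfactors[key] = max(bfactors.get(key, 0.0), float(val))
    out_prefix = Path(out_prefix)
    write_pdb(protein, out_prefix.with_suffix(".pdb"), bfactors=bfactors)
    payload = {
        "protein_id": protein.id,
        "ranking": ranking,
        "subpockets": [
            {"subpocket_id": s.subpocket_id, "pocket_rank": s.rank_k,
             "received_attention": float(scores[i]), "normalized": float(normed[i]),
             "residues": sorted({a.residue_index for a in s.atoms})}
            for i, s in enumerate(subs)],
        "global_drug_attention": summary.drug,
        "global_protein_attention": summary.protein,
    }
    out_prefix.with_suffix(".json").write_text(json.dumps(payload, indent=1))
    return payload


def per_token_table(summary: AttentionSummary, subpocket_ids: list[str]) -> list[dict]:
    """Line-plot-ready rows: token label, received attention, placeholder flag."""
    labels = ["gd", "gp"] + [f"s{i + 1}" for i in range(len(summary.received) - 2)]
    rows = []
    for i, label in enumerate(labels):
        sid = subpocket_ids[i - 2] if 2 <= i < 2 + len(subpocket_ids) else ""
        rows.append({"token": label, "subpocket_id": sid,
                     "received_attention": float(summary.received[i]),
                     "is_placeholder": bool(summary.placeholder_mask[i])})
    return rows
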
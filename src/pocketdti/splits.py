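"""Dataset split protocols and negative sampling.

Three evaluation regimes of increasing difficulty: a random 7:2:1 pair
split; unseen-entity splits where 20% of drugs (or proteins) and every pair
they touch go to the test fold; and a cross-domain split that clusters
drugs by ECFP4 Jaccard distance and proteins by sequence-composition cosine
distance with single linkage, sends pairs between 60% of drug clusters and
60% of protein clusters to the source (training) domain, and tests on 20%
of the remaining target-domain pairs.  All protocols are pure functions of
(input, seed).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .types import DrugRecord, InteractionPair, ProteinRecord

FOLDS = ("train", "valid", "test")


@dataclass
class SplitPlan:
    assignments: dict[InteractionPair, str]
    protocol: str
    seed: int

    def fold(self, name: str) -> list[InteractionPair]:
        return [p for p, f in self.assignments.items() if f == name]

    def audit_disjoint_exhaustive(self, pairs: list[InteractionPair]) -> None:
        if set(self.assignments) != set(pairs):
            raise AssertionError("split does not cover exactly the input pairs")
        if set(self.assignments.values()) - set(FOLDS):
            raise AssertionError("unknown fold labels present")


def random_split(pairs: list[InteractionPair], ratios: tuple[float, float, float] = (0.7, 0.2, 0.1),
                 seed: int = 0) -> SplitPlan:
    """Seeded pair-level shuffle into train/valid/test at the given ratios."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs to split")
    order = np.random.default_rng(seed).permutation(len(pairs))
    n = len(pairs)
    n_train = round(n * ratios[0])
    n_valid = round(n * ratios[1])
    assignments = {}
    for slot, idx in enumerate(order):
        fold = "train" if slot < n_train else "valid" if slot < n_train + n_valid else "test"
        assignments[pairs[idx]] = fold
    return SplitPlan(assignments, "random", seed)


def unseen_entity_split(pairs: list[InteractionPair], entity: str = "protein",
                        fraction: float = 0.2, seed: int = 0) -> SplitPlan:
    """Hold out a fraction of drugs or proteins, with all their pairs, as test.

    The remaining pairs are split train/valid at the 7:2 proportion of the
    random protocol.
    """
    if entity not in ("drug", "protein"):
        raise ValueError("entity must be 'drug' or 'protein'")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    key = (lambda p: p.drug_id) if entity == "drug" else (lambda p: p.protein_id)
    entities = sorted({key(p) for p in pairs})
    rng = np.random.default_rng(seed)
    n_test = int(np.ceil(fraction * len(entities)))
    test_entities = set(rng.permutation(entities)[:n_test])
    test_pairs = [p for p in pairs if key(p) in test_entities]
    rest = [p for p in pairs if key(p) not in test_entities]
    if not rest:
        raise ValueError("held-out entities own every pair; nothing left to train on")
    order = rng.permutation(len(rest))
    n_train = round(len(rest) * 7 / 9)
    assignments = {p: "test" for p in test_pairs}
    for slot, idx in enumerate(order):
        assignments[rest[idx]] = "train" if slot < n_train else "valid"
    return SplitPlan(assignments, f"unseen_{entity}", seed)


# ---------------------------------------------------------------------------
# cross-domain split
# ---------------------------------------------------------------------------

def ecfp4_fingerprints(drugs: list[DrugRecord], n_bits: int = 1024) -> np.ndarray:
    """Circular fingerprints of radius 2 (ECFP4), one bit row per drug."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    rows = np.zeros((len(drugs), n_bits), dtype=np.uint8)
    for i, d in enumerate(drugs):
        mol = Chem.MolFromSmiles(d.smiles)
        if mol is None:
            raise ValueError(f"{d.id}: unparsable SMILES")
        fp = gen.GetFingerprint(mol)
        rows[i, list(fp.GetOnBits())] = 1
    return rows


_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}


def sequence_composition(proteins: list[ProteinRecord]) -> np.ndarray:
    """Amino-acid + dipeptide composition features (20 + 400 = 420-d)."""
    rows = np.zeros((len(proteins), 20 + 400), dtype=np.float64)
    for i, p in enumerate(proteins):
        seq = [a for a in p.sequence if a in _AA_INDEX]
        for a in seq:
            rows[i, _AA_INDEX[a]] += 1
        for a, b in zip(seq, seq[1:]):
            rows[i, 20 + _AA_INDEX[a] * 20 + _AA_INDEX[b]] += 1
        if seq:
            rows[i, :20] /= len(seq)
        if len(seq) > 1:
            rows[i, 20:] /= len(seq) - 1
    return rows


def jaccard_distance_matrix(fps: np.ndarray) -> np.ndarray:
    inter = fps.astype(np.int32) @ fps.T.astype(np.int32)
    counts = fps.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    np.fill_diagonal(d, 0.0)
    return d


def cosine_distance_matrix(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    normed = x / np.maximum(norms, 1e-12)
    d = 1.0 - normed @ normed.T
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def single_linkage_clusters(dist: np.ndarray, threshold: float) -> np.ndarray:
    """Cluster labels from single-linkage agglomeration cut at ``threshold``."""
    if len(dist) == 1:
        return np.zeros(1, dtype=int)
    z = linkage(squareform(dist, checks=False), method="single")
    return fcluster(z, t=threshold, criterion="distance") - 1


def cross_domain_split(pairs: list[InteractionPair], drugs: list[DrugRecord],
                       proteins: list[ProteinRecord], seed: int = 0,
                       drug_threshold: float = 0.6, protein_threshold: float = 0.12,
                       source_cluster_fraction: float = 0.6,
                       target_test_fraction: float = 0.2,
                       valid_fraction: float = 0.125) -> SplitPlan:
    """Cluster-disjoint split into a source (train/valid) and target domain."""
    drug_labels = single_linkage_clusters(
        jaccard_distance_matrix(ecfp4_fingerprints(drugs)), drug_threshold)
    prot_labels = single_linkage_clusters(
        cosine_distance_matrix(sequence_composition(proteins)), protein_threshold)
    if len(set(drug_labels)) < 2:
        raise ValueError("all drugs fall in one cluster; lower drug_threshold")
    if len(set(prot_labels)) < 2:
        raise ValueError("all proteins fall in one cluster; lower protein_threshold")
    rng = np.random.default_rng(seed)
    drug_cluster_of = {d.id: drug_labels[i] for i, d in enumerate(drugs)}
    prot_cluster_of = {p.id: prot_labels[i] for i, p in enumerate(proteins)}

    def pick_source(labels: np.ndarray) -> set[int]:
        ids = sorted(set(labels))
        n_src = max(1, int(round(source_cluster_fraction * len(ids))))
        return set(rng.permutation(ids)[:n_src].tolist())

    src_drug_clusters = pick_source(drug_labels)
    src_prot_clusters = pick_source(prot_labels)
    source = [p for p in pairs if drug_cluster_of[p.drug_id] in src_drug_clusters
              and prot_cluster_of[p.protein_id] in src_prot_clusters]
    target = [p for p in pairs if p not in set(source)]
    if not source or not target:
        raise ValueError("degenerate source/target partition; adjust thresholds")

    assignments: dict[InteractionPair, str] = {}
    order = rng.permutation(len(source))
    n_valid = int(round(valid_fraction * len(source)))
    for slot, idx in enumerate(order):
        assignments[source[idx]] = "valid" if slot < n_valid else "train"
    t_order = rng.permutation(len(target))
    n_test = int(round(target_test_fraction * len(target)))
    for slot, idx in enumerate(t_order):
        assignments[target[idx]] = "test" if slot < n_test else "excluded"
    # pairs of the target domain outside the 20% test sample play no role
    assignments = {p: f for p, f in assignments.items() if f != "excluded"}
    return SplitPlan(assignments, "cross_domain", seed)


def sample_negatives(positives: list[InteractionPair], drug_ids: list[str],
                     protein_ids: list[str], ratio: float = 1.0,
                     seed: int = 0) -> list[InteractionPair]:
    """Uniformly sample unobserved (drug, protein) combinations as negatives."""
    n_needed = int(round(ratio * len(positives)))
    if n_needed == 0:
        return []
    observed = {(p.drug_id, p.protein_id) for p in positives}
    universe = len(drug_ids) * len(protein_ids)
    if universe - len(observed) < n_needed:
        raise ValueError(f"only {universe - len(observed)} unobserved combinations "
                         f"available, need {n_needed}")
    rng = np.random.default_rng(seed)
    chosen: list[InteractionPair] = []
    seen = set(observed)
    while len(chosen) < n_needed:
        d = drug_ids[rng.integers(len(drug_ids))]
        t = protein_ids[rng.integers(len(protein_ids))]
        if (d, t) not in seen:
            seen.add((d, t))
            chosen.append(InteractionPair(d, t, 0))
    return chosen
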
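"""Synthetic study data: toy structures with carved cavities, fragment-grammar
ligands, and interaction labels planted at the subpocket level.

Structures are geometric toys, not physical proteins: the C-alpha trace is
wound as a spherical spiral shell around each cavity centre (so the cavity
is a genuine enclosed void with lining atoms) and continued as a clash-free
random walk elsewhere.  Each cavity decomposes into 2-3 overlapping
spherical lobes — the ground-truth subpockets.  Lining residues of a lobe
are drawn mostly from the lobe's *signature* class (basic K/R, aromatic
F/W, or polar N/Q); ligands are assembled from a fragment grammar and may
carry the matching chemical motifs (carboxylate, benzene ring, amide).  A
pair is positive exactly when the ligand carries a motif whose signature
class lines one of the protein's subpockets; that subpocket is recorded as
the causal binding site, and labels are then flipped at the configured
noise rate.  Every output is a pure function of the FixtureSpec and its seed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem
from scipy.spatial import cKDTree

from . import io as pio
from .types import (AA1_TO_3, Atom, DrugRecord, InteractionPair,
                    PocketAssignmentFile, PocketEntry, ProteinRecord, Residue,
                    SubpocketEntry)

# motif SMILES -> signature class -> lining residue alphabet
MOTIF_SIGNATURES = {
    "C(=O)O": "basic",
    "c1ccccc1": "aromatic",
    "C(=O)N": "polar",
}
SIGNATURE_RESIDUES = {"basic": "KR", "aromatic": "FW", "polar": "NQ"}
FILLER_RESIDUES = "AGLVISTMEDCP"  # avoids every signature alphabet (and Y/H)

CA_STEP = 3.8            # consecutive C-alpha distance, Angstrom
LOBE_RADIUS = 3.0        # cavity lobe void radius
SHELL_RADIUS = 5.5       # winding radius of the cavity shell
CAPTURE_RADIUS = 6.0     # lobe centre -> subpocket atom cutoff
LINING_PROB = 0.85       # probability a lining residue carries the signature


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic benchmark."""
    n_proteins: int = 200
    n_drugs: int = 50
    n_pairs: int = 2000
    residue_range: tuple[int, int] = (52, 64)
    pockets_per_protein: int = 2
    subpockets_per_pocket: tuple[int, int] = (2, 3)
    signatures_per_protein: int = 2
    motif_prob: float = 0.293     # per-motif inclusion; ~balanced labels
    label_noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")


@dataclass
class CavitySpec:
    n_lobes: int = 2
    lobe_radius: float = LOBE_RADIUS
    lobe_spacing: float = 4.5


@dataclass
class GroundTruthSubpocket:
    subpocket_id: str
    signature: str
    center: np.ndarray
    atoms: list[tuple[int, str]]          # (residue index, atom name)
    lining_residues: list[int]


@dataclass
class GroundTruthPocket:
    pocket_id: str
    score: float
    subpockets: list[GroundTruthSubpocket]


# ---------------------------------------------------------------------------
# backbone geometry
# ---------------------------------------------------------------------------

def _spiral_shell(center: np.ndarray, n_points: int, radius: float,
                  rng: np.random.Generator) -> np.ndarray:
    """C-alpha positions on a spherical spiral with ~CA_STEP chords."""
    c = max(1.0, (n_points * CA_STEP) / (2.0 * radius))
    rot = _random_rotation(rng)
    pts = []
    theta = 0.25
    while len(pts) < n_points and theta < np.pi - 0.15:
        phi = c * theta
        p = radius * np.array([np.sin(theta) * np.cos(phi),
                               np.sin(theta) * np.sin(phi), np.cos(theta)])
        pts.append(center + rot @ p)
        theta += CA_STEP / (radius * np.sqrt(1.0 + (c * np.sin(theta)) ** 2))
    return np.array(pts)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])


def _walk(start: np.ndarray, heading: np.ndarray, n_steps: int,
          existing: list[np.ndarray], rng: np.random.Generator,
          voids: list[tuple[np.ndarray, float]]) -> np.ndarray:
    """Clash-free continuation: CA_STEP steps with persistent heading noise."""
    pts = []
    pos, h = start.copy(), heading / np.linalg.norm(heading)
    occupied = list(existing)
    for _ in range(n_steps):
        best, best_pen = None, np.inf
        for _try in range(24):
            d = h + 0.6 * rng.standard_normal(3)
            d /= np.linalg.norm(d)
            cand = pos + CA_STEP * d
            pen = 0.0
            if occupied:
                near = np.min(np.linalg.norm(np.asarray(occupied) - cand, axis=1))
                if near < 3.2:
                    pen += (3.2 - near) * 10
            for vc, vr in voids:
                gap = np.linalg.norm(cand - vc)
                if gap < vr + 1.0:
                    pen += (vr + 1.0 - gap) * 10
            if pen < best_pen:
                best_pen, best = pen, (cand, d)
            if pen == 0.0:
                break
        cand, d = best
        pts.append(cand)
        occupied.append(cand)
        pos, h = cand, d
    return np.array(pts)


def _equalize_steps(ca: np.ndarray, voids: list[tuple[np.ndarray, float]],
                    n_iter: int = 120) -> np.ndarray:
    """Gauss-Seidel relaxation pulling consecutive C-alpha distances to
    CA_STEP while keeping points out of the carved voids."""
    ca = ca.copy()
    for _ in range(n_iter):
        worst = 0.0
        for i in range(len(ca) - 1):
            d = ca[i + 1] - ca[i]
            dist = np.linalg.norm(d)
            err = dist - CA_STEP
            worst = max(worst, abs(err))
            shift = 0.5 * err * d / (dist + 1e-12)
            ca[i] += shift
            ca[i + 1] -= shift
        for vc, vr in voids:
            delta = ca - vc
            dist = np.linalg.norm(delta, axis=1)
            inside = dist < vr + 0.4
            if inside.any():
                ca[inside] = vc + delta[inside] * ((vr + 0.4) / dist[inside])[:, None]
        if worst < 0.02:
            break
    return ca


def _place_atoms(ca: np.ndarray) -> list[list[Atom]]:
    """Backbone N/CA/C/O plus CB from the local chain frame (toy geometry)."""
    n = len(ca)
    atoms_per_res = []
    for i in range(n):
        u_prev = ca[i] - ca[i - 1] if i > 0 else ca[min(i + 1, n - 1)] - ca[i]
        u_next = ca[i + 1] - ca[i] if i < n - 1 else u_prev
        u_prev = u_prev / (np.linalg.norm(u_prev) + 1e-12)
        u_next = u_next / (np.linalg.norm(u_next) + 1e-12)
        ref = np.array([0.0, 0.0, 1.0]) if abs(u_next[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        v = np.cross(u_next, ref)
        v /= np.linalg.norm(v) + 1e-12
        w = np.cross(u_next, v)
        atoms = [
            Atom("N", "N", tuple(ca[i] - 1.46 * u_prev)),
            Atom("CA", "C", tuple(ca[i])),
            Atom("C", "C", tuple(ca[i] + 1.52 * u_next)),
            Atom("O", "O", tuple(ca[i] + 1.52 * u_next + 1.23 * v)),
            Atom("CB", "C", tuple(ca[i] + 1.52 * w)),
        ]
        atoms_per_res.append(atoms)
    return atoms_per_res


def make_structure(n_residues: int, cavities: list[CavitySpec], seed: int,
                   protein_id: str = "toy") -> tuple[ProteinRecord, list[GroundTruthPocket]]:
    """Toy single-chain structure with carved, lobed cavities.

    Returns the record plus ground truth: per cavity a pocket whose
    subpockets are the lobes, with their lining atoms.  Sequence letters are
    filler; callers may overwrite them (signatures are planted later).
    """
    if n_residues < 20:
        raise ValueError("n_residues must be >= 20")
    rng = np.random.default_rng(seed)
    shell_budget = sum(max(10, 7 * c.n_lobes) for c in cavities) + 4 * len(cavities)
    if shell_budget > n_residues:
        raise ValueError(f"{n_residues} residues cannot enclose {len(cavities)} "
                         f"cavities (need >= {shell_budget})")

    centers = [np.zeros(3)]
    for _ in cavities[1:]:
        d = rng.standard_normal(3)
        centers.append(centers[-1] + (2 * SHELL_RADIUS + 4.0) * d / np.linalg.norm(d))

    lobe_centers: list[list[np.ndarray]] = []
    voids: list[tuple[np.ndarray, float]] = []
    for center, cav in zip(centers, cavities):
        axis = _random_rotation(rng)[:, 0]
        lobes = [center + (k - (cav.n_lobes - 1) / 2.0) * cav.lobe_spacing * axis
                 for k in range(cav.n_lobes)]
        lobe_centers.append(lobes)
        voids.extend((lc, cav.lobe_radius) for lc in lobes)

    ca_blocks: list[np.ndarray] = []
    for ci, (center, cav) in enumerate(zip(centers, cavities)):
        n_shell = max(10, 7 * cav.n_lobes)
        shell = _spiral_shell(center, n_shell, SHELL_RADIUS + (cav.n_lobes - 1) * 1.2, rng)
        if ca_blocks:
            prev_end = ca_blocks[-1][-1]
            gap_dir = shell[0] - prev_end
            n_gap = max(2, int(np.linalg.norm(gap_dir) / CA_STEP))
            connector = np.array([prev_end + gap_dir * (k / n_gap)
                                  for k in range(1, n_gap)])
            ca_blocks.append(connector)
        ca_blocks.append(shell)
    ca = np.concatenate(ca_blocks) if ca_blocks else np.zeros((1, 3))
    remaining = n_residues - len(ca)
    if remaining > 0:
        heading = ca[-1] - ca[-2] if len(ca) > 1 else np.array([1.0, 0.0, 0.0])
        tail = _walk(ca[-1], heading, remaining, list(ca), rng, voids)
        ca = np.concatenate([ca, tail])
    ca = _equalize_steps(ca[:n_residues], voids)

    atoms_per_res = _place_atoms(ca)
    residues = [Residue(i + 1, "ALA", atoms) for i, atoms in enumerate(atoms_per_res)]
    flat = [(r.index, a.name, np.array(a.coords)) for r in residues for a in r.atoms]
    coords = np.array([c for *_, c in flat])
    tree = cKDTree(coords)

    pockets: list[GroundTruthPocket] = []
    for ci, lobes in enumerate(lobe_centers):
        subs = []
        for li, lc in enumerate(lobes):
            idx = sorted(tree.query_ball_point(lc, CAPTURE_RADIUS))
            # an atom shared by several lobes belongs to the nearest one
            mine = [i for i in idx if li == int(np.argmin(
                [np.linalg.norm(coords[i] - other) for other in lobes]))]
            if len(mine) < 5:
                continue
            atom_ids = [(flat[i][0], flat[i][1]) for i in mine]
            lining = sorted({flat[i][0] for i in mine})
            subs.append(GroundTruthSubpocket(f"p{ci}s{li}", "", lc, atom_ids, lining))
        if subs:
            pockets.append(GroundTruthPocket(f"p{ci}", 0.0, subs))

    record = ProteinRecord(protein_id, "A" * n_residues, residues)
    record.validate()
    return record, pockets


def make_convex_structure(n_residues: int = 30, seed: int = 0,
                          protein_id: str = "rod") -> ProteinRecord:
    """Extended zig-zag chain with no cavity (negative control for detection)."""
    rng = np.random.default_rng(seed)
    ca = np.array([[i * CA_STEP, 1.0 * (i % 2), 0.0] for i in range(n_residues)])
    ca = ca + 0.05 * rng.standard_normal(ca.shape)
    residues = [Residue(i + 1, "ALA", atoms)
                for i, atoms in enumerate(_place_atoms(ca))]
    return ProteinRecord(protein_id, "A" * n_residues, residues)


# ---------------------------------------------------------------------------
# ligands
# ---------------------------------------------------------------------------

def make_ligands(n: int, motifs: list[str], seed: int,
                 motif_prob: float = FixtureSpec.motif_prob,
                 atom_range: tuple[int, int] = (8, 25)
                 ) -> tuple[list[DrugRecord], dict[str, set[str]]]:
    """Random chain molecules with motif branches; returns records plus the
    motif set each ligand was built to contain (verified by substructure)."""
    rng = np.random.default_rng(seed)
    drugs, drug_motifs = [], {}
    for i in range(n):
        included = {m for m in motifs if rng.random() < motif_prob}
        motif_atoms = sum(Chem.MolFromSmiles(m).GetNumAtoms() for m in included)
        target = rng.integers(atom_range[0], atom_range[1] + 1)
        chain_len = int(np.clip(target - motif_atoms, 4, atom_range[1] - motif_atoms))
        positions = sorted(rng.choice(np.arange(1, chain_len), size=len(included),
                                      replace=False)) if included else []
        motif_list = sorted(included)
        pos_iter = {int(p): m for p, m in zip(positions, motif_list)}
        smiles_parts = []
        for j in range(chain_len):
            # heteroatoms only away from branch points (keeps valences legal)
            if j not in pos_iter and rng.random() < 0.15:
                smiles_parts.append("O" if rng.random() < 0.5 else "N")
            else:
                smiles_parts.append("C")
            if j in pos_iter:
                smiles_parts.append(f"({pos_iter[j]})")
        smiles = "".join(smiles_parts)
        mol = Chem.MolFromSmiles(smiles)
        assert mol is not None, smiles
        for m in included:
            assert mol.HasSubstructMatch(Chem.MolFromSmiles(m))
        rec = DrugRecord(f"D{i:04d}", smiles)
        drugs.append(rec)
        drug_motifs[rec.id] = included
    return drugs, drug_motifs


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass
class FixtureDataset:
    spec: FixtureSpec
    drugs: list[DrugRecord]
    proteins: list[ProteinRecord]
    pairs: list[InteractionPair]
    assignments: dict[str, PocketAssignmentFile]
    drug_motifs: dict[str, set[str]]
    protein_truth: dict[str, list[GroundTruthPocket]]
    causal_subpocket: dict[tuple[str, str], str]   # (drug, protein) -> subpocket id
    clean_labels: dict[tuple[str, str], int]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pio.write_pairs(self.drugs, self.proteins, self.pairs, out / "pairs.tsv")
        pio.write_pocket_assignments(self.assignments, out / "pockets.tsv")
        pdb_dir = out / "structures"
        pdb_dir.mkdir(exist_ok=True)
        for p in self.proteins:
            pio.write_pdb(p, pdb_dir / f"{p.id}.pdb")
        truth = {
            "drug_motifs": {k: sorted(v) for k, v in self.drug_motifs.items()},
            "causal_subpocket": {f"{d}|{p}": s for (d, p), s in self.causal_subpocket.items()},
            "clean_labels": {f"{d}|{p}": y for (d, p), y in self.clean_labels.items()},
            "signatures": {
                pid: {s.subpocket_id: s.signature for pk in pockets for s in pk.subpockets}
                for pid, pockets in self.protein_truth.items()},
        }
        (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))


def _plant_signatures(record: ProteinRecord, pockets: list[GroundTruthPocket],
                      signatures: list[str], rng: np.random.Generator) -> None:
    """Assign a signature to every subpocket and rewrite lining residues."""
    seq = list(rng.choice(list(FILLER_RESIDUES), size=len(record.structure)))
    flat_subs = [s for pk in pockets for s in pk.subpockets]
    rng.shuffle(flat_subs)  # signature-to-lobe arrangement varies per protein
    for i, sub in enumerate(flat_subs):
        # every declared signature appears at least once; extras draw randomly
        sub.signature = signatures[i] if i < len(signatures) \
            else signatures[rng.integers(len(signatures))]
    for sub in flat_subs:
        alphabet = SIGNATURE_RESIDUES[sub.signature]
        for res_idx in sub.lining_residues:
            if rng.random() < LINING_PROB:
                seq[res_idx - 1] = alphabet[rng.integers(len(alphabet))]
    record.sequence = "".join(seq)
    for res, aa in zip(record.structure, record.sequence):
        res.name = AA1_TO_3[aa]


def _score_pockets(pockets: list[GroundTruthPocket], rng: np.random.Generator) -> None:
    """Ligandability score ~ lining size on a fixed scale plus mild noise, so
    scores stay strongly rank-correlated with bindability across proteins."""
    sizes = np.array([sum(len(s.atoms) for s in pk.subpockets) for pk in pockets], dtype=float)
    noisy = np.clip(sizes / 100.0 + 0.03 * rng.standard_normal(len(pockets)), 0.01, 1.5)
    for pk, sc in zip(pockets, noisy):
        pk.score = round(float(sc), 4)


def make_dataset(spec: FixtureSpec = FixtureSpec()) -> FixtureDataset:
    """Generate the full labelled study dataset from a FixtureSpec, seeded."""
    root = np.random.SeedSequence(spec.seed)
    prot_seeds, drug_seed, pair_seed = root.spawn(3)
    rng = np.random.default_rng(pair_seed)

    motifs = list(MOTIF_SIGNATURES)
    drugs, drug_motifs = make_ligands(spec.n_drugs, motifs,
                                      int(drug_seed.generate_state(1)[0] % 2**31),
                                      spec.motif_prob)

    proteins, truth, assignments = [], {}, {}
    prot_rngs = prot_seeds.spawn(spec.n_proteins)
    for i, ss in enumerate(prot_rngs):
        prng = np.random.default_rng(ss)
        n_res = int(prng.integers(*spec.residue_range))
        cavs = [CavitySpec(n_lobes=int(prng.integers(spec.subpockets_per_pocket[0],
                                                     spec.subpockets_per_pocket[1] + 1)))
                for _ in range(spec.pockets_per_protein)]
        pid = f"P{i:04d}"
        seed_i = int(ss.generate_state(1)[0] % 2**31)
        record, pockets = make_structure(n_res, cavs, seed_i, pid)
        sigs = list(prng.choice(sorted(SIGNATURE_RESIDUES), size=spec.signatures_per_protein,
                                replace=False))
        _plant_signatures(record, pockets, sigs, prng)
        _score_pockets(pockets, prng)
        proteins.append(record)
        truth[pid] = pockets
        assignments[pid] = PocketAssignmentFile(pid, [
            PocketEntry(pk.pocket_id, pk.score,
                        [SubpocketEntry(s.subpocket_id, list(s.atoms))
                         for s in pk.subpockets])
            for pk in pockets])

    # label rule: positive iff some ligand motif's signature lines a subpocket
    prot_signatures = {p.id: {s.signature for pk in truth[p.id] for s in pk.subpockets}
                       for p in proteins}
    combos = [(d.id, p.id) for d in drugs for p in proteins]
    chosen = rng.permutation(len(combos))[:spec.n_pairs]
    pairs, causal, clean = [], {}, {}
    ranked_order = {
        pid: sorted(((pk.score, s) for pk in truth[pid] for s in pk.subpockets),
                    key=lambda t: -t[0])
        for pid in truth}
    for idx in chosen:
        did, pid = combos[idx]
        match_sigs = {MOTIF_SIGNATURES[m] for m in drug_motifs[did]} & prot_signatures[pid]
        label = int(bool(match_sigs))
        clean[(did, pid)] = label
        if label:
            for _score, sub in ranked_order[pid]:
                if sub.signature in match_sigs:
                    causal[(did, pid)] = sub.subpocket_id
                    break
        if rng.random() < spec.label_noise:
            label = 1 - label
        pairs.append(InteractionPair(did, pid, label))

    return FixtureDataset(spec, drugs, proteins, pairs, assignments, drug_motifs,
                          truth, causal, clean)
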
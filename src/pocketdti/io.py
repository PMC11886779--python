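"""Readers and writers for every on-disk format the pipeline touches.

Formats: PDB structures (ATOM records only), delimited drug-protein pair
datasets (columns ``smiles``, ``sequence``, ``label``), pocket/subpocket
assignment tables exported by a cavity-detection tool, fold-assignment split
files, and prediction tables.  All delimited files accept tab or comma
separation with an optional header.
"""
from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .types import (AA3_TO_1, Atom, DrugRecord, InteractionPair, PocketAssignmentFile,
                    PocketEntry, ProteinRecord, Residue, SubpocketEntry)

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

_WATER = {"HOH", "WAT", "DOD"}


class PDBParseError(ValueError):
    pass


class EmptyStructureError(ValueError):
    pass


class PairFileError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path, protein_id: str | None = None) -> ProteinRecord:
    """Parse the first chain of a PDB file into a :class:`ProteinRecord`.

    HETATM records and waters are excluded.  Only the first alternate
    location of an atom is kept; insertion codes are rejected because the
    canonical residue key is the plain PDB residue number.
    """
    path = Path(path)
    residues: list[Residue] = []
    atoms_by_res: dict[int, list[Atom]] = {}
    names_by_res: dict[int, str] = {}
    seen_atoms: set[tuple[int, str]] = set()
    first_chain: str | None = None
    other_chains = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.startswith("ATOM"):
            continue
        try:
            name = line[12:16].strip()
            altloc = line[16].strip()
            resname = line[17:20].strip()
            chain = line[21].strip()
            resseq = int(line[22:26])
            icode = line[26].strip()
            x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
            element = line[76:78].strip() or name[0]
        except (ValueError, IndexError) as err:
            raise PDBParseError(f"{path.name}: malformed ATOM record at line {lineno}: {err}") from err
        if resname in _WATER:
            continue
        if icode:
            raise PDBParseError(f"{path.name}: insertion code {icode!r} at line {lineno} is unsupported")
        if first_chain is None:
            first_chain = chain
        if chain != first_chain:
            other_chains = True
            continue
        if altloc and (resseq, name) in seen_atoms:
            continue  # keep first altloc only
        if (resseq, name) in seen_atoms:
            continue
        seen_atoms.add((resseq, name))
        atoms_by_res.setdefault(resseq, []).append(Atom(name, element, (x, y, z)))
        names_by_res.setdefault(resseq, resname)
    if other_chains:
        logger.warning("%s: multiple chains present; keeping chain %r only", path.name, first_chain)
    if not atoms_by_res:
        raise EmptyStructureError(f"{path.name}: no ATOM records (protein) found")
    for resseq in sorted(atoms_by_res):
        residues.append(Residue(resseq, names_by_res[resseq], atoms_by_res[resseq]))
    sequence = "".join(AA3_TO_1.get(r.name, "X") for r in residues)
    record = ProteinRecord(protein_id or path.stem, sequence, residues)
    record.validate()
    return record


def write_pdb(protein: ProteinRecord, path: str | Path,
              bfactors: dict[tuple[int, str], float] | None = None,
              chain: str = "A") -> None:
    """Write a ProteinRecord as PDB ATOM records.

    ``bfactors`` optionally maps (residue index, atom name) to a value for
    the temperature-factor column (used by the attention projection).
    """
    lines = []
    serial = 1
    for res in protein.structure:
        for atom in res.atoms:
            b = 0.0 if bfactors is None else bfactors.get((res.index, atom.name), 0.0)
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            lines.append(
                f"ATOM  {serial:>5d} {name:<4.4s} {res.name:<3s} {chain}{res.index:>4d}    "
                f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
                f"{1.00:6.2f}{b:6.2f}          {atom.element:>2s}")
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# pair datasets (columns: smiles, sequence, label)
# ---------------------------------------------------------------------------

def _read_delimited(path: Path, columns: list[str]) -> pd.DataFrame:
    sep = "\t" if "\t" in path.read_text().splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    first = [str(v).strip().lower() for v in df.iloc[0]]
    if set(columns) <= set(first):
        df = pd.read_csv(path, sep=sep, dtype=str, comment="#")
        df.columns = [c.strip().lower() for c in df.columns]
    else:
        if df.shape[1] < len(columns):
            raise PairFileError(f"{path.name}: expected >= {len(columns)} columns, found {df.shape[1]}")
        df = df.iloc[:, :len(columns)]
        df.columns = columns
    return df


def read_pairs(path: str | Path) -> tuple[list[DrugRecord], list[ProteinRecord], list[InteractionPair]]:
    """Read a delimited interaction dataset and deduplicate its entities.

    Returns drug records, sequence-only protein stubs (no structure) and the
    labelled pairs.  Rows whose SMILES does not parse are skipped with a
    logged warning; a non-binary label is a hard error naming the row.
    """
    path = Path(path)
    df = _read_delimited(path, ["smiles", "sequence", "label"])
    drugs: dict[str, DrugRecord] = {}
    proteins: dict[str, ProteinRecord] = {}
    pairs: list[InteractionPair] = []
    skipped = 0
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        smiles, sequence, label_raw = str(row.smiles).strip(), str(row.sequence).strip(), str(row.label).strip()
        try:
            label = int(float(label_raw))
        except ValueError:
            raise PairFileError(f"{path.name}: row {row_no}: non-numeric label {label_raw!r}")
        if label not in (0, 1):
            raise PairFileError(f"{path.name}: row {row_no}: label must be 0 or 1, got {label_raw!r}")
        if Chem.MolFromSmiles(smiles) is None:
            skipped += 1
            logger.warning("%s: row %d: unparsable SMILES %r skipped", path.name, row_no, smiles)
            continue
        if smiles not in drugs:
            drugs[smiles] = DrugRecord(f"D{len(drugs):04d}", smiles)
        if sequence not in proteins:
            proteins[sequence] = ProteinRecord(f"P{len(proteins):04d}", sequence)
        pairs.append(InteractionPair(drugs[smiles].id, proteins[sequence].id, label))
    if skipped:
        logger.warning("%s: skipped %d rows with unparsable SMILES", path.name, skipped)
    return list(drugs.values()), list(proteins.values()), pairs


def write_pairs(drugs: list[DrugRecord], proteins: list[ProteinRecord],
                pairs: list[InteractionPair], path: str | Path) -> None:
    dmap = {d.id: d.smiles for d in drugs}
    pmap = {p.id: p.sequence for p in proteins}
    df = pd.DataFrame({
        "smiles": [dmap[p.drug_id] for p in pairs],
        "sequence": [pmap[p.protein_id] for p in pairs],
        "label": [p.label for p in pairs],
    })
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pocket assignment files
# ---------------------------------------------------------------------------

_POCKET_COLS = ["protein_id", "pocket_id", "caviar_score", "subpocket_id",
                "residue_index", "atom_name"]


def read_pocket_assignments(path: str | Path) -> dict[str, PocketAssignmentFile]:
    """Read a pocket/subpocket assignment table, one file per dataset.

    Dialect: delimited columns protein_id, pocket_id, caviar_score,
    subpocket_id, residue_index, atom_name; one row per subpocket atom.
    A pocket listed with two different scores is an error.
    """
    path = Path(path)
    df = _read_delimited(path, _POCKET_COLS)
    out: dict[str, PocketAssignmentFile] = {}
    for protein_id, pdf in df.groupby("protein_id", sort=False):
        pockets: list[PocketEntry] = []
        for pocket_id, kdf in pdf.groupby("pocket_id", sort=False):
            scores = sorted({float(s) for s in kdf.caviar_score})
            if len(scores) > 1:
                raise ValueError(
                    f"{path.name}: pocket {pocket_id!r} of {protein_id!r} has "
                    f"inconsistent scores {scores}")
            subs = [SubpocketEntry(str(sid), [(int(r.residue_index), str(r.atom_name))
                                              for r in sdf.itertuples(index=False)])
                    for sid, sdf in kdf.groupby("subpocket_id", sort=False)]
            for s in subs:
                if not s.atoms:
                    raise ValueError(f"{path.name}: subpocket {s.subpocket_id!r} has no atoms")
            pockets.append(PocketEntry(str(pocket_id), scores[0], subs))
        out[str(protein_id)] = PocketAssignmentFile(str(protein_id), pockets)
    return out


def write_pocket_assignments(assignments: dict[str, PocketAssignmentFile],
                             path: str | Path) -> None:
    rows = []
    for paf in assignments.values():
        for pocket in paf.pockets:
            for sub in pocket.subpockets:
                for res_idx, atom_name in sub.atoms:
                    rows.append((paf.protein_id, pocket.pocket_id, pocket.score,
                                 sub.subpocket_id, res_idx, atom_name))
    pd.DataFrame(rows, columns=_POCKET_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# splits and predictions
# ---------------------------------------------------------------------------

def write_split(assignments: dict[InteractionPair, str], path: str | Path) -> None:
    rows = [(p.drug_id, p.protein_id, p.label, fold) for p, fold in assignments.items()]
    pd.DataFrame(rows, columns=["drug_id", "protein_id", "label", "fold"]).to_csv(
        path, sep="\t", index=False)


def read_split(path: str | Path) -> dict[InteractionPair, str]:
    df = _read_delimited(Path(path), ["drug_id", "protein_id", "label", "fold"])
    out: dict[InteractionPair, str] = {}
    for row in df.itertuples(index=False):
        fold = str(row.fold)
        if fold not in {"train", "valid", "test"}:
            raise ValueError(f"unknown fold {fold!r}")
        out[InteractionPair(str(row.drug_id), str(row.protein_id), int(row.label))] = fold
    return out


def write_predictions(pairs: list[InteractionPair], probabilities: list[float],
                      top_subpockets: list[str], path: str | Path) -> None:
    """Write per-pair predictions with the top-attended subpocket id."""
    if not (len(pairs) == len(probabilities) == len(top_subpockets)):
        raise ValueError(
            f"length mismatch: {len(pairs)} pairs, {len(probabilities)} probabilities, "
            f"{len(top_subpockets)} attention summaries")
    df = pd.DataFrame({
        "drug_id": [p.drug_id for p in pairs],
        "protein_id": [p.protein_id for p in pairs],
        "label": [p.label for p in pairs],
        "probability": probabilities,
        "top_subpocket": top_subpockets,
    })
    df.to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
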
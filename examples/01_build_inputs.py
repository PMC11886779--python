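"""Build the model's inputs for one drug-protein pair.

Generates a small toy structure with a carved two-lobe cavity, embeds the
protein and a ligand with the deterministic stub providers, and prints the
shapes of every object the interaction model consumes.
"""
from pocketdti.embeddings import DRUG_DIM, PROTEIN_DIM, embed_drug, embed_protein, stub_provider
from pocketdti.graphs import build_drug_graph, build_residue_graph, residue_properties
from pocketdti.pockets import pockets_from_assignment, subpocket_set_graphs
from pocketdti.synthetic import CavitySpec, make_structure
from pocketdti.types import (DrugRecord, PocketAssignmentFile, PocketEntry,
                             SubpocketEntry)

protein, truth = make_structure(56, [CavitySpec(n_lobes=2)], seed=7, protein_id="demo")
print(f"protein: {len(protein.structure)} residues, {protein.n_atoms} atoms, "
      f"{len(truth)} ground-truth pocket(s)")

prot_emb = embed_protein(protein.sequence, stub_provider(PROTEIN_DIM, seed=0))
residue_graph = build_residue_graph(protein, prot_emb, residue_properties(protein.sequence))
print(f"residue graph: {residue_graph.n_nodes} nodes x {residue_graph.feature_dim} features, "
      f"{len(residue_graph.edges)} typed edges (peptide / H-bond / KNN)")

drug = DrugRecord("demo-drug", "CCC(c1ccccc1)CCC(=O)O")
atom_emb, alignment = embed_drug(drug.smiles, stub_provider(DRUG_DIM, seed=1))
drug_graph = build_drug_graph(drug, atom_emb)
print(f"drug graph: {drug_graph.n_nodes} heavy atoms, {len(drug_graph.edges)} bonds; "
      f"{len(alignment.unmatched)} non-atom SMILES tokens ignored")

# the ground truth doubles as a pocket assignment file; real data would come
# from a cavity-detection export or the geometric fallback detector
assignment = PocketAssignmentFile(protein.id, [
    PocketEntry(pk.pocket_id, 0.9, [SubpocketEntry(s.subpocket_id, list(s.atoms))
                                    for s in pk.subpockets])
    for pk in truth])
pockets = pockets_from_assignment(assignment, protein)
subset, graphs = subpocket_set_graphs(pockets, protein, M=30)
print(f"subpocket set: {len(subset.subpockets)} real subpockets + "
      f"{subset.placeholders} placeholders = M={subset.M} graphs")
print("positional indices (parent-pocket ranks) of the first slots:", subset.ranks[:6])
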
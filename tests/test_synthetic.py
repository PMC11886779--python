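"""Synthetic study-data generator: geometry audits, planted labels, noise."""
import numpy as np
import pytest
from rdkit import Chem

from pocketdti import io as pio
from pocketdti.synthetic import (MOTIF_SIGNATURES, SIGNATURE_RESIDUES, CavitySpec,
                                 FixtureSpec, make_dataset, make_ligands,
                                 make_structure)


class TestMakeStructure:
    def test_residue_count_and_lining_recorded(self):
        record, truth = make_structure(56, [CavitySpec(2)], seed=0)
        assert len(record.structure) == 56
        assert truth and all(s.atoms for p in truth for s in p.subpockets)

    def test_same_seed_identical_coordinates(self):
        a, _ = make_structure(52, [CavitySpec(2)], seed=3)
        b, _ = make_structure(52, [CavitySpec(2)], seed=3)
        assert np.array_equal(a.coords(), b.coords())

    @pytest.mark.parametrize("seed", range(5))
    def test_consecutive_ca_distances_within_tolerance(self, seed):
        record, _ = make_structure(56, [CavitySpec(2), CavitySpec(3)], seed=seed)
        ca = np.array([r.atom("CA").coords for r in record.structure])
        d = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.all(np.abs(d - 3.8) <= 0.2)

    def test_infeasible_cavity_budget_rejected(self):
        with pytest.raises(ValueError, match="cannot enclose"):
            make_structure(20, [CavitySpec(3), CavitySpec(3)], seed=0)

    def test_structures_parse_under_io_and_independent_reader(self, tmp_path):
        import biotite.structure.io.pdb as bpdb
        record, _ = make_structure(52, [CavitySpec(2)], seed=1)
        path = tmp_path / "s.pdb"
        pio.write_pdb(record, path)
        assert pio.read_pdb(path).n_atoms == record.n_atoms
        arr = bpdb.PDBFile.read(str(path)).get_structure(model=1)
        assert len(arr) == record.n_atoms


class TestMakeLigands:
    def test_all_parse_and_declared_motifs_present(self):
        drugs, motifs = make_ligands(10, list(MOTIF_SIGNATURES), seed=0)
        assert len(drugs) == 10
        for d in drugs:
            mol = Chem.MolFromSmiles(d.smiles)
            assert mol is not None
            for m in motifs[d.id]:
                assert mol.HasSubstructMatch(Chem.MolFromSmiles(m))

    def test_heavy_atom_counts_in_range(self):
        drugs, _ = make_ligands(300, list(MOTIF_SIGNATURES), seed=1)
        counts = [Chem.MolFromSmiles(d.smiles).GetNumAtoms() for d in drugs]
        assert min(counts) >= 8 and max(counts) <= 25

    def test_undeclared_motifs_absent(self):
        """The planted rule is exact: no ligand accidentally contains a
        motif it was not built with."""
        drugs, motifs = make_ligands(100, list(MOTIF_SIGNATURES), seed=2)
        for d in drugs:
            mol = Chem.MolFromSmiles(d.smiles)
            for m in MOTIF_SIGNATURES:
                if m not in motifs[d.id]:
                    assert not mol.HasSubstructMatch(Chem.MolFromSmiles(m)), \
                        (d.smiles, m)


@pytest.fixture(scope="module")
def ds1000():
    return make_dataset(FixtureSpec(n_proteins=40, n_drugs=30, n_pairs=1000,
                                    label_noise=0.1, seed=21))


class TestMakeDataset:

    def test_zero_noise_labels_follow_rule_exactly(self):
        spec = FixtureSpec(n_proteins=10, n_drugs=10, n_pairs=80,
                           label_noise=0.0, seed=5)
        ds = make_dataset(spec)
        sigs = {p.id: {s.signature for pk in ds.protein_truth[p.id]
                       for s in pk.subpockets} for p in ds.proteins}
        for pair in ds.pairs:
            match = {MOTIF_SIGNATURES[m] for m in ds.drug_motifs[pair.drug_id]} \
                & sigs[pair.protein_id]
            assert pair.label == int(bool(match))

    def test_flip_fraction_within_binomial_interval(self, ds1000):
        flipped = sum(p.label != ds1000.clean_labels[(p.drug_id, p.protein_id)]
                      for p in ds1000.pairs)
        assert 0.07 <= flipped / len(ds1000.pairs) <= 0.13

    def test_class_balance_near_half(self):
        ds = make_dataset(FixtureSpec(n_proteins=60, n_drugs=40, n_pairs=1500, seed=2))
        mean = np.mean([p.label for p in ds.pairs])
        assert 0.4 <= mean <= 0.6

    def test_scores_track_bindability(self, ds1000):
        """Assignment-file scores correlate with ground-truth lining size."""
        from scipy.stats import spearmanr
        sizes, scores = [], []
        for pid, pockets in ds1000.protein_truth.items():
            for pk in pockets:
                sizes.append(sum(len(s.atoms) for s in pk.subpockets))
                scores.append(pk.score)
        rho = spearmanr(sizes, scores).statistic
        assert rho >= 0.8

    def test_causal_subpocket_named_for_clean_positives(self, ds1000):
        for (d, p), y in ds1000.clean_labels.items():
            if y == 1:
                assert (d, p) in ds1000.causal_subpocket

    def test_lining_sequences_carry_signatures(self, ds1000):
        protein = ds1000.proteins[0]
        truth = ds1000.protein_truth[protein.id]
        for pk in truth:
            for s in pk.subpockets:
                letters = [protein.sequence[r - 1] for r in s.lining_residues]
                alphabet = set(SIGNATURE_RESIDUES[s.signature])
                frac = np.mean([aa in alphabet for aa in letters])
                assert frac >= 0.5

    def test_write_round_trips_through_io(self, tmp_path):
        ds = make_dataset(FixtureSpec(n_proteins=4, n_drugs=5, n_pairs=16, seed=9))
        ds.write(tmp_path)
        drugs, proteins, pairs = pio.read_pairs(tmp_path / "pairs.tsv")
        assert len(pairs) == 16
        assignments = pio.read_pocket_assignments(tmp_path / "pockets.tsv")
        assert set(assignments) == {p.id for p in ds.proteins}
        assert (tmp_path / "ground_truth.json").exists()
        assert len(list((tmp_path / "structures").glob("*.pdb"))) == 4

    def test_byte_identical_regeneration(self, tmp_path):
        spec = FixtureSpec(n_proteins=3, n_drugs=4, n_pairs=10, seed=13)
        make_dataset(spec).write(tmp_path / "a")
        make_dataset(spec).write(tmp_path / "b")
        for name in ("pairs.tsv", "pockets.tsv", "ground_truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()
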
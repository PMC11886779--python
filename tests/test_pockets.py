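"""Subpocket modeling: ranking, capping, fragment filter, graphs, detector."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pocketdti import pockets as pk
from pocketdti.synthetic import CavitySpec, make_convex_structure, make_structure


def _pocket(pid, score, n_subs=1):
    subs = [pk.Subpocket(f"{pid}_s{i}", pid, []) for i in range(n_subs)]
    return pk.Pocket(pid, score, subs)


def _atoms_at(coords):
    return [pk.SubpocketAtom(i + 1, "CA", "C", np.asarray(c, dtype=float))
            for i, c in enumerate(coords)]


class TestRankPockets:
    def test_descending_order_and_ranks(self):
        ranked = pk.rank_pockets([_pocket("a", 0.2), _pocket("b", 0.9), _pocket("c", 0.5)])
        assert [p.pocket_id for p in ranked] == ["b", "c", "a"]
        assert [p.rank for p in ranked] == [1, 2, 3]

    def test_single_pocket_rank_one(self):
        assert pk.rank_pockets([_pocket("only", 0.1)])[0].rank == 1

    def test_matches_brute_force_sort_with_stable_ties(self, rng):
        scores = rng.choice([0.1, 0.25, 0.5, 0.9], size=100)
        inputs = [_pocket(f"p{i}", float(s)) for i, s in enumerate(scores)]
        ranked = pk.rank_pockets(inputs)
        oracle = [p.pocket_id for _, _, p in
                  sorted(((-p.score, i, p) for i, p in enumerate(inputs)),
                         key=lambda t: t[:2])]
        assert [p.pocket_id for p in ranked] == oracle

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_monotone_scores_property(self, scores):
        ranked = pk.rank_pockets([_pocket(f"p{i}", s) for i, s in enumerate(scores)])
        out = [p.score for p in ranked]
        assert all(a >= b for a, b in zip(out, out[1:]))
        assert sorted(p.rank for p in ranked) == list(range(1, len(scores) + 1))

    def test_non_finite_score_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            pk.rank_pockets([_pocket("p", float("nan"))])


class TestSelectSubpockets:
    def test_greedy_fill_across_pockets(self):
        ranked = pk.rank_pockets([_pocket("a", 0.9, 2), _pocket("b", 0.5, 3)])
        subset = pk.select_subpockets(ranked, M=4)
        assert [s.subpocket_id for s in subset.subpockets] == \
            ["a_s0", "a_s1", "b_s0", "b_s1"]
        assert subset.placeholders == 0
        assert [s.rank_k for s in subset.subpockets] == [1, 1, 2, 2]

    def test_three_subpockets_m30_pads_27_placeholders(self):
        """One pocket of three subpockets with the default cap of 30."""
        subset = pk.select_subpockets(pk.rank_pockets([_pocket("p", 1.0, 3)]), M=30)
        assert len(subset.subpockets) == 3 and subset.placeholders == 27

    def test_no_pockets_all_placeholders(self):
        subset = pk.select_subpockets([], M=5)
        assert subset.subpockets == [] and subset.placeholders == 5
        assert subset.ranks == [0] * 5

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.floats(0, 1), st.integers(0, 5)), max_size=8),
           st.integers(1, 12))
    def test_cap_conservation_property(self, config, m):
        ranked = pk.rank_pockets([_pocket(f"p{i}", s, n) for i, (s, n) in enumerate(config)])
        subset = pk.select_subpockets(ranked, M=m)
        assert len(subset.subpockets) + subset.placeholders == m
        assert len(subset.subpockets) <= m


class TestFilterFragments:
    def _sub(self, sizes, gap=10.0):
        """Build fragments of the given sizes as 1.5-A-spaced chains."""
        coords = []
        for fi, size in enumerate(sizes):
            for a in range(size):
                coords.append([fi * gap, a * 1.5, 0.0])
        return pk.Subpocket("s", "p", _atoms_at(coords))

    def test_small_fragments_dropped(self):
        out = pk.filter_fragments(self._sub([7, 4, 2]))
        assert len(out.atoms) == 7

    def test_exactly_five_atoms_retained(self):
        out = pk.filter_fragments(self._sub([5]))
        assert len(out.atoms) == 5

    def test_all_fragments_small_drops_subpocket(self):
        assert pk.filter_fragments(self._sub([4, 3])) is None

    def test_never_adds_atoms(self):
        sub = self._sub([6, 2])
        out = pk.filter_fragments(sub)
        ids_in = {(a.residue_index, a.atom_name) for a in sub.atoms}
        ids_out = {(a.residue_index, a.atom_name) for a in out.atoms}
        assert ids_out <= ids_in


class TestSubpocketGraph:
    def test_covalent_edge_below_threshold(self):
        sub = pk.Subpocket("s", "p", _atoms_at([[0, 0, 0], [1.5, 0, 0]]))
        graph = pk.build_subpocket_graph(sub, np.zeros((2, 4), np.float32))
        assert len(graph.edges) == 1 and graph.edge_types[0] == 0

    def test_distant_atoms_disconnected(self):
        sub = pk.Subpocket("s", "p", _atoms_at([[0, 0, 0], [5.0, 0, 0]]))
        graph = pk.build_subpocket_graph(sub, np.zeros((2, 4), np.float32))
        assert len(graph.edges) == 0 and graph.n_nodes == 2

    def test_edges_match_all_pairs_distance_oracle(self, rng):
        coords = rng.uniform(0, 8, size=(20, 3))
        sub = pk.Subpocket("s", "p", _atoms_at(coords))
        graph = pk.build_subpocket_graph(sub, np.zeros((20, 4), np.float32))
        got = {(int(i), int(j), int(t)) for (i, j), t
               in zip(graph.edges, graph.edge_types)}
        expected = set()
        for i in range(20):
            for j in range(i + 1, 20):
                d = np.linalg.norm(coords[i] - coords[j])
                if d <= 2.0:
                    expected.add((i, j, 0))   # covalent proxy
                elif d <= 4.5:
                    expected.add((i, j, 1))   # contact
        assert got == expected


class TestPlaceholder:
    def test_single_zero_node_no_edges(self):
        ph = pk.make_placeholder(8)
        assert ph.n_nodes == 1 and ph.node_features.sum() == 0
        assert len(ph.edges) == 0 and ph.is_placeholder

    def test_invalid_dim_rejected(self):
        with pytest.raises(ValueError):
            pk.make_placeholder(0)


@pytest.fixture(scope="module")
def carved():
    return make_structure(60, [CavitySpec(2)], seed=5, protein_id="carved")


class TestGeometricDetector:
    def test_finds_cavity_overlapping_ground_truth(self, carved):
        record, truth = carved
        found = pk.detect_pockets_geometric(record)
        assert len(found) >= 1
        truth_atoms = {a for p in truth for s in p.subpockets for a in s.atoms}
        best = max(
            len({(a.residue_index, a.atom_name) for s in p.subpockets
                 for a in s.atoms} & truth_atoms)
            / len({(a.residue_index, a.atom_name) for s in p.subpockets
                   for a in s.atoms} | truth_atoms)
            for p in found)
        assert best >= 0.3

    def test_convex_structure_yields_no_pockets(self):
        assert pk.detect_pockets_geometric(make_convex_structure(30, seed=0)) == []

    def test_stable_under_grid_refinement(self, carved):
        record, _ = carved
        coarse = pk.detect_pockets_geometric(record)
        fine = pk.detect_pockets_geometric(record, grid_spacing=0.5)
        a = {(x.residue_index, x.atom_name) for s in coarse[0].subpockets for x in s.atoms}
        b = {(x.residue_index, x.atom_name) for s in fine[0].subpockets for x in s.atoms}
        assert len(a & b) / len(a | b) >= 0.8

    def test_too_small_structure_advises_assignment_file(self):
        record, _ = make_structure(20, [], seed=1)
        record.structure = record.structure[:3]
        with pytest.raises(ValueError, match="assignment file"):
            pk.detect_pockets_geometric(record)


def test_full_preprocessing_emits_exactly_m_graphs(tiny_dataset):
    protein = tiny_dataset.proteins[0]
    pockets = pk.pockets_from_assignment(
        tiny_dataset.assignments[protein.id], protein)
    subset, graphs = pk.subpocket_set_graphs(pockets, protein, M=30)
    assert len(graphs) == 30
    n_ph = sum(1 for g in graphs if g.is_placeholder)
    assert len(subset.subpockets) + n_ph == 30
    assert n_ph == subset.placeholders
    assert len(subset.ranks) == 30


def test_unresolvable_atom_identifier_raises_join_error(tiny_dataset):
    from pocketdti.types import PocketAssignmentFile, PocketEntry, SubpocketEntry
    protein = tiny_dataset.proteins[0]
    bad = PocketAssignmentFile(protein.id, [
        PocketEntry("p", 0.5, [SubpocketEntry("s", [(9999, "CA")])])])
    with pytest.raises(pk.JoinError, match="9999"):
        pk.pockets_from_assignment(bad, protein)
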
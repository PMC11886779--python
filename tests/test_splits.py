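"""Split protocols: fold arithmetic, leakage audits, clustering oracle,
negative sampling, and metric oracles."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import roc_auc_score

from pocketdti import splits as sp
from pocketdti.metrics import best_f1_threshold, evaluate
from pocketdti.types import DrugRecord, InteractionPair, ProteinRecord


def _pairs(n_drugs=10, n_prots=10, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for d in range(n_drugs):
        for p in range(n_prots):
            out.append(InteractionPair(f"D{d}", f"P{p}", int(rng.integers(2))))
    return out


class TestRandomSplit:
    def test_100_pairs_split_70_20_10(self):
        plan = sp.random_split(_pairs(10, 10), seed=1)
        sizes = {f: len(plan.fold(f)) for f in ("train", "valid", "test")}
        assert sizes == {"train": 70, "valid": 20, "test": 10}

    def test_same_seed_identical(self):
        pairs = _pairs()
        assert sp.random_split(pairs, seed=3).assignments == \
            sp.random_split(pairs, seed=3).assignments

    def test_partition_exhaustive_and_disjoint(self):
        pairs = _pairs(7, 9)
        plan = sp.random_split(pairs, seed=0)
        plan.audit_disjoint_exhaustive(pairs)
        folds = [set(plan.fold(f)) for f in ("train", "valid", "test")]
        assert folds[0] | folds[1] | folds[2] == set(pairs)
        assert not (folds[0] & folds[1] or folds[0] & folds[2] or folds[1] & folds[2])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            sp.random_split(_pairs(1, 2), seed=0)


class TestUnseenEntitySplit:
    def test_held_out_proteins_never_seen_in_training(self):
        plan = sp.unseen_entity_split(_pairs(10, 10), "protein", 0.2, seed=0)
        test_prots = {p.protein_id for p in plan.fold("test")}
        train_prots = {p.protein_id for p in plan.fold("train") + plan.fold("valid")}
        assert len(test_prots) == 2
        assert test_prots & train_prots == set()

    @pytest.mark.parametrize("entity", ["drug", "protein"])
    def test_leakage_audit_both_entities(self, entity):
        plan = sp.unseen_entity_split(_pairs(8, 12, seed=4), entity, 0.25, seed=2)
        key = (lambda p: p.drug_id) if entity == "drug" else (lambda p: p.protein_id)
        assert {key(p) for p in plan.fold("test")} & \
            {key(p) for p in plan.fold("train") + plan.fold("valid")} == set()

    def test_single_entity_selection_takes_all_its_pairs(self):
        pairs = [InteractionPair("D0", f"P{i}", 1) for i in range(3)]
        pairs += [InteractionPair("D1", f"P{i}", 0) for i in range(6)]
        plan = sp.unseen_entity_split(pairs, "drug", 0.5, seed=0)
        assert len(plan.fold("test")) in (3, 6)

    def test_entity_owning_everything_rejected(self):
        pairs = [InteractionPair("D0", f"P{i}", 1) for i in range(4)]
        with pytest.raises(ValueError):
            sp.unseen_entity_split(pairs, "drug", 0.5, seed=0)


@pytest.fixture(scope="module")
def families():
    # two chemically distinct drug families, two protein families
    drugs = [DrugRecord(f"D{i}", s) for i, s in enumerate(
        ["CCCCCCCC", "CCCCCCC", "CCCCCCCCC", "CCCCCC",
         "c1ccccc1O", "c1ccccc1N", "c1ccccc1C", "c1ccccc1CC"])]
    proteins = [ProteinRecord(f"P{i}", seq) for i, seq in enumerate(
        ["MKLVMKLVMKLV" * 3, "MKLVMKLVMKLA" * 3, "MKLVMKLVMKLG" * 3,
         "WWDDEEWWDDEE" * 3, "WWDDEEWWDDEA" * 3, "WWDDEEWWDDEG" * 3])]
    rng = np.random.default_rng(0)
    pairs = [InteractionPair(d.id, p.id, int(rng.integers(2)))
             for d in drugs for p in proteins]
    return drugs, proteins, pairs


class TestCrossDomainSplit:
    def test_every_test_pair_has_out_of_source_entity(self, families):
        drugs, proteins, pairs = families
        plan = sp.cross_domain_split(pairs, drugs, proteins, seed=1)
        train = plan.fold("train") + plan.fold("valid")
        src_drugs = {p.drug_id for p in train}
        src_prots = {p.protein_id for p in train}
        for pair in plan.fold("test"):
            assert pair.drug_id not in src_drugs or pair.protein_id not in src_prots

    def test_seeded_cluster_selection_reproducible(self, families):
        drugs, proteins, pairs = families
        a = sp.cross_domain_split(pairs, drugs, proteins, seed=5)
        b = sp.cross_domain_split(pairs, drugs, proteins, seed=5)
        assert a.assignments == b.assignments

    def test_single_linkage_merge_order_matches_brute_force(self):
        """4-point oracle: enumerate all merges by hand via the minimal
        inter-cluster single-link distance."""
        dist = np.array([
            [0.0, 0.1, 0.9, 0.8],
            [0.1, 0.0, 0.85, 0.95],
            [0.9, 0.85, 0.0, 0.2],
            [0.8, 0.95, 0.2, 0.0]])
        z = linkage(squareform(dist), method="single")
        # brute force: clusters {0},{1},{2},{3}; merges at 0.1 (0,1),
        # 0.2 (2,3), then 0.8 between the two pairs
        assert z[0][2] == pytest.approx(0.1)
        assert z[1][2] == pytest.approx(0.2)
        assert z[2][2] == pytest.approx(0.8)
        labels = sp.single_linkage_clusters(dist, threshold=0.5)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_degenerate_single_cluster_advises_threshold(self, families):
        drugs, proteins, pairs = families
        with pytest.raises(ValueError, match="threshold"):
            sp.cross_domain_split(pairs, drugs, proteins, seed=0,
                                  drug_threshold=1.01)


class TestSampleNegatives:
    def test_balanced_sampling_disjoint_from_positives(self):
        positives = [InteractionPair(f"D{i}", f"P{i}", 1) for i in range(5)]
        negs = sp.sample_negatives(positives, [f"D{i}" for i in range(5)],
                                   [f"P{i}" for i in range(5)], ratio=1.0, seed=0)
        assert len(negs) == 5
        assert all(n.label == 0 for n in negs)
        assert {(n.drug_id, n.protein_id) for n in negs} & \
            {(p.drug_id, p.protein_id) for p in positives} == set()

    def test_zero_ratio_empty(self):
        assert sp.sample_negatives([InteractionPair("D", "P", 1)], ["D"], ["P"],
                                   ratio=0.0, seed=0) == []

    def test_exhausted_universe_rejected(self):
        positives = [InteractionPair(f"D{d}", f"P{p}", 1)
                     for d in range(3) for p in range(3)]
        with pytest.raises(ValueError):
            sp.sample_negatives(positives, [f"D{i}" for i in range(3)],
                                [f"P{i}" for i in range(3)], ratio=1.0, seed=0)

    def test_pure_function_of_seed(self):
        positives = [InteractionPair("D0", "P0", 1)]
        args = (positives, [f"D{i}" for i in range(9)], [f"P{i}" for i in range(9)])
        assert sp.sample_negatives(*args, ratio=3.0, seed=7) == \
            sp.sample_negatives(*args, ratio=3.0, seed=7)


class TestMetrics:
    def test_perfect_separation_auc_one(self):
        rep = evaluate([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert rep.roc_auc == 1.0

    def test_constant_scores_auc_half(self):
        rep = evaluate([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert rep.roc_auc == 0.5

    def test_roc_auc_equals_mann_whitney_oracle(self, rng):
        """Concordant-pair count with half credit for ties, 100 random sets."""
        for _ in range(100):
            n = int(rng.integers(8, 30))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            pos, neg = scores[labels == 1], scores[labels == 0]
            conc = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            oracle = conc / (len(pos) * len(neg))
            assert abs(roc_auc_score(labels, scores) - oracle) < 1e-10

    def test_threshold_chosen_on_validation_only(self):
        v_labels, v_scores = [0, 0, 1, 1], [0.1, 0.4, 0.6, 0.9]
        rep = evaluate([1, 0], [0.7, 0.3], v_labels, v_scores)
        assert rep.threshold == best_f1_threshold(np.array(v_labels), np.array(v_scores))
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_single_class_fold_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            evaluate([1, 1, 1], [0.2, 0.5, 0.8])


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.integers(3, 40), st.integers(0, 2 ** 31 - 1))
def test_split_purity_property(n, seed):
    """Every protocol is a pure function of (input, seed) and partitions."""
    rng = np.random.default_rng(n)
    pairs = [InteractionPair(f"D{rng.integers(6)}", f"P{rng.integers(6)}", 1)
             for _ in range(n)]
    pairs = list(dict.fromkeys(pairs))
    if len(pairs) < 3:
        return
    a = sp.random_split(pairs, seed=seed)
    b = sp.random_split(pairs, seed=seed)
    assert a.assignments == b.assignments
    a.audit_disjoint_exhaustive(pairs)
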
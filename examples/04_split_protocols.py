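"""The three evaluation protocols, from easiest to hardest.

A random pair split measures interpolation; an unseen-protein split
measures generalisation to new targets; a cluster-based cross-domain split
measures transfer to chemically and biologically dissimilar data.  The
script prints fold sizes and verifies the leakage guarantees.
"""
from pocketdti.splits import cross_domain_split, random_split, unseen_entity_split
from pocketdti.synthetic import FixtureSpec, make_dataset

dataset = make_dataset(FixtureSpec(n_proteins=60, n_drugs=40, n_pairs=900, seed=8))
pairs, drugs, proteins = dataset.pairs, dataset.drugs, dataset.proteins

plan = random_split(pairs, seed=0)
print("random 7:2:1      ->", {f: len(plan.fold(f)) for f in ("train", "valid", "test")})

plan = unseen_entity_split(pairs, "protein", fraction=0.2, seed=0)
test_prots = {p.protein_id for p in plan.fold("test")}
train_prots = {p.protein_id for p in plan.fold("train") + plan.fold("valid")}
print("unseen-protein    ->", {f: len(plan.fold(f)) for f in ("train", "valid", "test")},
      f"| {len(test_prots)} held-out proteins, overlap with training: "
      f"{len(test_prots & train_prots)}")

plan = cross_domain_split(pairs, drugs, proteins, seed=0)
train_pairs = plan.fold("train") + plan.fold("valid")
src_d = {p.drug_id for p in train_pairs}
src_p = {p.protein_id for p in train_pairs}
leaks = sum(p.drug_id in src_d and p.protein_id in src_p for p in plan.fold("test"))
print("cross-domain      ->", {f: len(plan.fold(f)) for f in ("train", "valid", "test")},
      f"| test pairs fully inside source clusters: {leaks}")
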
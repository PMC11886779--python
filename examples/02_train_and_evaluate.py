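"""Train the model on a reduced synthetic benchmark and evaluate it.

Uses a smaller dataset than the full study (60 proteins, 30 drugs, 600
pairs) so the script finishes in about a minute; the full conditions are in
scripts/acceptance.py.  Prints the learning curve and the held-out metric
report: ROC-AUC and PR-AUC summarise ranking quality, and sensitivity /
specificity are taken at the best-F1 threshold found on validation.
"""
from pocketdti.embeddings import DRUG_DIM, PROTEIN_DIM, stub_provider
from pocketdti.model import DTIModel, ModelConfig, featurize
from pocketdti.splits import random_split
from pocketdti.synthetic import FixtureSpec, make_dataset
from pocketdti.train import TrainConfig, evaluate_fold, train

dataset = make_dataset(FixtureSpec(n_proteins=60, n_drugs=30, n_pairs=600, seed=4))
data = featurize(dataset.drugs, dataset.proteins, dataset.assignments,
                 stub_provider(PROTEIN_DIM, 1), stub_provider(DRUG_DIM, 2), M=30)
plan = random_split(dataset.pairs, seed=0)
print(f"{len(plan.fold('train'))} train / {len(plan.fold('valid'))} valid / "
      f"{len(plan.fold('test'))} test pairs")

model = DTIModel(ModelConfig(), seed=0)
result = train(model, data, plan, TrainConfig(epochs=10, seed=0))
for h in result.history:
    print(f"epoch {h.epoch:2d}: train BCE {h.train_loss:.3f}  "
          f"valid ROC-AUC {h.valid_roc_auc:.3f}")
print(f"checkpoint from epoch {result.best_epoch} "
      f"(valid ROC-AUC {result.best_valid_roc_auc:.3f})")

report = evaluate_fold(model, data, plan, "test")
print("held-out:", {k: round(v, 3) for k, v in report.as_dict().items()})
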
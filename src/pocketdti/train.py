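"""Training loop: minibatch Adam on binary cross-entropy with
validation-ROC-AUC model selection.

Defaults mirror the study conditions: batch size 32, learning rate 1e-4,
up to 30 epochs.  After every epoch the model is scored on the validation
fold and the parameter state with the best validation ROC-AUC is the one
returned.  Optional early stopping halts training when validation ROC-AUC
has not improved for ``patience`` epochs (the model typically converges
well before the epoch cap).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .interaction import bce_loss
from .metrics import MetricReport, evaluate
from .model import DTIModel, FeaturizedDataset
from .nn.layers import Adam
from .splits import SplitPlan

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    batch_size: int = 32
    epochs: int = 30
    learning_rate: float = 1e-4
    seed: int = 0
    patience: int | None = 6   # early stop after this many non-improving epochs

    def __post_init__(self):
        if min(self.batch_size, self.epochs) < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size, epochs and learning_rate must be positive")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    valid_roc_auc: float


@dataclass
class TrainResult:
    history: list[EpochRecord]
    best_epoch: int
    best_valid_roc_auc: float


def _scores(model: DTIModel, pairs, data) -> tuple[np.ndarray, np.ndarray]:
    labels = np.array([p.label for p in pairs])
    return labels, model.predict(pairs, data)


def train(model: DTIModel, data: FeaturizedDataset, plan: SplitPlan,
          config: TrainConfig = TrainConfig()) -> TrainResult:
    """Fit in place; on return the model holds the best-validation weights."""
    train_pairs = plan.fold("train")
    valid_pairs = plan.fold("valid")
    if not train_pairs or not valid_pairs:
        raise ValueError("train and valid folds must be non-empty")
    rng = np.random.default_rng(config.seed)
    dropout_rng = np.random.default_rng(config.seed + 1)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    history: list[EpochRecord] = []
    best_state, best_auc, best_epoch = model.state_dict(), -np.inf, 0
    stale = 0
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(train_pairs))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [train_pairs[i] for i in order[start:start + config.batch_size]]
            labels = np.array([p.label for p in batch])
            optimizer.zero_grad()
            probs = model.forward(batch, data, training=True, rng=dropout_rng)
            loss = bce_loss(labels, probs)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {float(loss.data)}; "
                    "check inputs and learning rate")
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        v_labels, v_scores = _scores(model, valid_pairs, data)
        v_auc = float(roc_auc_score(v_labels, v_scores))
        history.append(EpochRecord(epoch, float(np.mean(losses)), v_auc))
        logger.info("epoch %d: train loss %.4f, valid ROC-AUC %.4f", epoch,
                    history[-1].train_loss, v_auc)
        if v_auc > best_auc:
            best_auc, best_epoch, best_state = v_auc, epoch, model.state_dict()
            stale = 0
        else:
            stale += 1
            if config.patience is not None and stale >= config.patience:
                logger.info("early stop at epoch %d (no improvement for %d epochs)",
                            epoch, stale)
                break
    model.load_state_dict(best_state)
    return TrainResult(history, best_epoch, best_auc)


def evaluate_fold(model: DTIModel, data: FeaturizedDataset, plan: SplitPlan,
                  fold: str = "test") -> MetricReport:
    """Metric report on a fold, thresholded at the validation best-F1 point."""
    pairs = plan.fold(fold)
    v_pairs = plan.fold("valid")
    labels, scores = _scores(model, pairs, data)
    v_labels, v_scores = _scores(model, v_pairs, data)
    return evaluate(labels, scores, v_labels, v_scores)
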
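"""Training loop with the embedding freeze/unfreeze schedule, plus
AUROC/AUPR evaluation on the original imbalanced test split.

The embedding table is frozen for the first two epochs at learning rate
1e-3; from the third epoch onward it is unfrozen and the rate drops to
1e-4 (a single multi-step milestone at the unfreeze epoch, factor 0.1).
Model selection is on validation AUPR.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator
from sklearn.metrics import average_precision_score, roc_auc_score

from .model import EPINTLM, bce_loss
from .nn import Adam, no_grad
from .pipeline import SeqGenDataset

logger = logging.getLogger(__name__)


class TrainConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    batch_size: int = 256
    weight_decay: float = 0.001
    lr_initial: float = 1e-3
    lr_after_unfreeze: float = 1e-4
    freeze_epochs: int = 2
    max_epochs: int = 15
    early_stop_patience: int = 3
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if not self.lr_after_unfreeze < self.lr_initial:
            raise ValueError("lr_after_unfreeze must be below lr_initial")
        if self.freeze_epochs < 0:
            raise ValueError("freeze_epochs must be >= 0")
        return self


def training_schedule(epoch: int, config: TrainConfig) -> tuple[bool, float]:
    """(embedding_trainable, learning_rate) for a 1-based epoch index.

    Epochs 1..freeze_epochs: frozen at ``lr_initial``; afterwards
    trainable at ``lr_after_unfreeze``.
    """
    if epoch < 1:
        raise ValueError(f"epoch must be >= 1, got {epoch}")
    if epoch <= config.freeze_epochs:
        return False, config.lr_initial
    return True, config.lr_after_unfreeze


@dataclass
class TrainHistory:
    """Per-epoch training record (one dict per epoch)."""

    seed: int
    epochs: list[dict] = dc_field(default_factory=list)

    def append(self, **row) -> None:
        self.epochs.append(row)

    def to_jsonl(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            for row in self.epochs:
                fh.write(json.dumps(row) + "\n")
        return path


# -- metrics ---------------------------------------------------------------

def auroc(scores, labels) -> float:
    """Area under the ROC curve; equals the Mann-Whitney statistic
    P(score_pos > score_neg) + 0.5 P(tie)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores)))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve in the average-precision
    (precision-weighted recall-step sum) form."""
    labels = np.asarray(labels)
    if not np.any(labels == 1):
        raise ValueError("AUPR needs at least one positive")
    return float(average_precision_score(labels, np.asarray(scores)))


# -- batching and prediction ----------------------------------------------

def _batches(n: int, batch_size: int, rng: Optional[np.random.Generator] = None):
    idx = np.arange(n)
    if rng is not None:
        rng.shuffle(idx)
    for lo in range(0, n, batch_size):
        chunk = idx[lo:lo + batch_size]
        if rng is not None and len(chunk) < 2:
            continue  # batch statistics need >= 2 samples
        yield chunk


def predict(model: EPINTLM, ds: SeqGenDataset, batch_size: int = 256) -> np.ndarray:
    """Interaction probabilities in dataset order (inference mode)."""
    model.eval()
    out = np.empty(len(ds), dtype=np.float64)
    with no_grad():
        for chunk in _batches(len(ds), batch_size):
            probs, _ = model(ds.I_E[chunk], ds.I_P[chunk], ds.G[chunk])
            out[chunk] = probs.data
    return out


def evaluate(model: EPINTLM, ds: SeqGenDataset, batch_size: int = 256) -> dict:
    """AUROC/AUPR report on a dataset (meant for the original test split)."""
    scores = predict(model, ds, batch_size)
    y = np.asarray(ds.y)
    return {"auroc": auroc(scores, y), "aupr": aupr(scores, y),
            "n_pos": int((y == 1).sum()), "n_neg": int((y == 0).sum())}


# -- training --------------------------------------------------------------

def train(model: EPINTLM, train_ds: SeqGenDataset, val_ds: SeqGenDataset,
          config: TrainConfig | None = None) -> TrainHistory:
    """Train with the freeze/unfreeze schedule; restores the best
    checkpoint (validation AUPR) into ``model`` before returning.

    Fit and validation datasets must not share pair ids.
    """
    config = config or TrainConfig()
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise ValueError("empty train or validation split")
    overlap = set(map(str, train_ds.pair_ids)) & set(map(str, val_ds.pair_ids))
    if overlap:
        raise ValueError(f"pair ids leak across the fit/val boundary: "
                         f"{sorted(overlap)[:5]}...")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7121]))
    optimizer = Adam(model.parameters(), lr=config.lr_initial,
                     weight_decay=config.weight_decay)
    history = TrainHistory(seed=config.seed)
    best = {"aupr": -np.inf, "params": None, "epoch": 0}
    stale = 0

    for epoch in range(1, config.max_epochs + 1):
        trainable, lr = training_schedule(epoch, config)
        model.set_embedding_trainable(trainable)
        optimizer.lr = lr

        model.train()
        losses = []
        for chunk in _batches(len(train_ds), config.batch_size, rng):
            probs, _ = model(train_ds.I_E[chunk], train_ds.I_P[chunk],
                             train_ds.G[chunk])
            loss = bce_loss(probs, train_ds.y[chunk])
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))

        val_scores = predict(model, ds=val_ds, batch_size=config.batch_size)
        val_y = np.asarray(val_ds.y)
        val_loss = float(-np.mean(
            val_y * np.log(val_scores + 1e-7)
            + (1 - val_y) * np.log(1 - val_scores + 1e-7)))
        row = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "val_loss": val_loss,
            "val_auroc": auroc(val_scores, val_y),
            "val_aupr": aupr(val_scores, val_y),
            "lr": lr,
            "embedding_trainable": trainable,
        }
        history.append(**row)
        logger.info("epoch %d: %s", epoch, json.dumps(row))

        if row["val_aupr"] > best["aupr"]:
            best = {"aupr": row["val_aupr"], "epoch": epoch,
                    "params": {k: v.data.copy()
                               for k, v in _all_params(model).items()},
                    "bn": _bn_stats(model)}
            stale = 0
        else:
            stale += 1
            if stale >= config.early_stop_patience:
                logger.info("early stop at epoch %d (best epoch %d)",
                            epoch, best["epoch"])
                break

    if best["params"] is not None:
        for k, v in _all_params(model).items():
            v.data[...] = best["params"][k]
        for (name, bn), stats in zip(_named_bns(model), best["bn"]):
            bn.running_mean, bn.running_var = (s.copy() for s in stats)
    model.eval()
    return history


def _all_params(model: EPINTLM) -> dict:
    named = model.named_parameters()
    named.setdefault("embedding", model.embedding)
    return named


def _named_bns(model):
    from .model import _iter_batchnorms
    return list(_iter_batchnorms(model))


def _bn_stats(model):
    return [(bn.running_mean.copy(), bn.running_var.copy())
            for _, bn in _named_bns(model)]
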
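"""Deterministic training loop for the contact-prototype head.

Mirrors the reference regimen — AdamW, learning rate 1e−3, batch size 512,
150 epochs, dropout 0.2, class-weighted binary cross-entropy — at arbitrary
scale. A fixed seed fixes initialization, data order, and dropout masks, so
two runs produce bit-identical checkpoints.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .autodiff import Tensor
from .embeddings import EmbeddingStore, assemble_batch
from .errors import NonFiniteLossError
from .layers import ContactMap, bce_loss
from .model import ContactHead, HeadConfig

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization hyperparameters; defaults follow the reference regimen."""

    epochs: int = 150
    batch_size: int = 512
    learning_rate: float = 1e-3
    weight_decay: float = 0.01
    betas: tuple = (0.9, 0.999)
    adam_eps: float = 1e-8
    dropout: float = 0.2
    seed: int = 0
    pos_weight: object = "auto"       # "auto" → N_neg / N_pos of the training set
    grad_clip: float = 1.0            # global-norm clip; 0 disables
    val_fraction: float = 0.1         # epitope fraction held out for checkpointing
    n_thresholds: int = 10
    tied: bool = False
    normalize_by_valid: bool = False  # score w by L1·L2 instead of N²

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size, learning_rate must be positive")


class AdamW:
    """Decoupled-weight-decay Adam over a list of tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                         + self.wd * p.data)


def clip_global_norm(params: Sequence[Tensor], max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``."""
    total = math.sqrt(sum(float(np.sum(p.grad ** 2))
                          for p in params if p.grad is not None))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return total


def auto_pos_weight(records) -> float:
    """Negative:positive count ratio of a record list (≥ one of each)."""
    labels = np.array([r.label for r in records])
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return 1.0
    return n_neg / n_pos


@dataclass
class TrainResult:
    head: ContactHead
    history: list              # per-epoch dicts: epoch, loss, val_loss, lr
    best_epoch: int
    pos_weight: float


def _epitope_val_split(records, fraction: float, rng: np.random.Generator):
    epitopes = sorted({r.epitope_id for r in records})
    n_val = int(round(fraction * len(epitopes)))
    if n_val == 0 or n_val >= len(epitopes):
        return list(records), []
    val_set = set(rng.choice(epitopes, size=n_val, replace=False))
    train = [r for r in records if r.epitope_id not in val_set]
    val = [r for r in records if r.epitope_id in val_set]
    if not any(r.label == 1 for r in train) or not train:
        return list(records), []
    return train, val


def _mean_loss(head: ContactHead, records, store, pos_weight, batch_size):
    total, n = 0.0, 0
    for i in range(0, len(records), batch_size):
        chunk = records[i:i + batch_size]
        batch = assemble_batch(chunk, store)
        y_hat, _, _ = head.forward(batch, training=False)
        loss = bce_loss(head.calibrate(y_hat), batch.labels, pos_weight)
        total += loss.item() * len(chunk)
        n += len(chunk)
    return total / max(n, 1)


def train(records, store: EmbeddingStore, config: TrainConfig,
          checkpoint_path=None) -> TrainResult:
    """Fit a head on triplet records backed by an embedding store.

    Holds out ``val_fraction`` of epitopes for checkpoint selection (the
    lowest-validation-loss epoch is retained; with no validation split the
    final epoch is kept). Aborts on a non-finite loss with a dump of the
    offending batch.
    """
    records = list(records)
    for r in records:
        for seq in r.triple:
            if seq not in store:
                from .errors import StoreLookupError
                raise StoreLookupError(f"sequence {seq!r} missing from store")

    rng = np.random.default_rng(config.seed)
    train_recs, val_recs = _epitope_val_split(records, config.val_fraction, rng)
    pos_weight = (auto_pos_weight(train_recs) if config.pos_weight == "auto"
                  else float(config.pos_weight))

    head = ContactHead(HeadConfig(
        dimension=store.dimension, max_length=store.max_length,
        n_thresholds=config.n_thresholds, dropout=config.dropout,
        tied=config.tied, normalize_by_valid=config.normalize_by_valid,
        init_seed=int(rng.integers(2 ** 31))))
    opt = AdamW(head.parameters(), lr=config.learning_rate, betas=config.betas,
                eps=config.adam_eps, weight_decay=config.weight_decay)

    history = []
    best = (math.inf, -1, None)   # (val loss, epoch, saved arrays)
    order = np.arange(len(train_recs))
    for epoch in range(config.epochs):
        rng.shuffle(order)
        epoch_loss, seen = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            chunk = [train_recs[j] for j in idx]
            batch = assemble_batch(chunk, store)
            head.zero_grad()
            y_hat, _, _ = head.forward(batch, training=True, rng=rng)
            loss = bce_loss(head.calibrate(y_hat), batch.labels, pos_weight)
            if not np.isfinite(loss.item()):
                raise NonFiniteLossError(
                    f"non-finite loss at epoch {epoch}, batch offset {i}",
                    batch_dump={"records": chunk, "y_hat": y_hat.data.copy(),
                                "epoch": epoch, "offset": i})
            loss.backward()
            clip_global_norm(head.parameters(), config.grad_clip)
            opt.step()
            epoch_loss += loss.item() * len(chunk)
            seen += len(chunk)
        epoch_loss /= max(seen, 1)
        val_loss = (_mean_loss(head, val_recs, store, pos_weight,
                               config.batch_size) if val_recs else epoch_loss)
        history.append({"epoch": epoch, "loss": epoch_loss,
                        "val_loss": val_loss, "lr": config.learning_rate})
        logger.info("epoch %d: loss %.5f val %.5f", epoch, epoch_loss, val_loss)
        if val_loss < best[0]:
            best = (val_loss, epoch,
                    {k: t.data.copy() for k, t in head.named_parameters().items()})

    if best[2] is not None:
        for k, t in head.named_parameters().items():
            t.data = best[2][k]
    if checkpoint_path is not None:
        head.save(checkpoint_path)
    return TrainResult(head=head, history=history, best_epoch=best[1],
                       pos_weight=pos_weight)


@dataclass
class Prediction:
    record: object
    y_hat: float
    map_a: ContactMap            # axes (peptide, cdr3b)
    map_b: ContactMap            # axes (peptide, cdr3a)


def predict_dataset(records, store: EmbeddingStore, head: ContactHead,
                    batch_size: int = 256) -> list[Prediction]:
    """Deterministic inference (no dropout); output is independent of
    batching and ordering up to floating-point associativity."""
    out = []
    for i in range(0, len(records), batch_size):
        chunk = list(records[i:i + batch_size])
        batch = assemble_batch(chunk, store)
        y_hat, maps_a, maps_b = head.predict_batch(batch)
        for rec, yh, ma, mb in zip(chunk, y_hat, maps_a, maps_b):
            out.append(Prediction(record=rec, y_hat=float(yh),
                                  map_a=ma, map_b=mb))
    return out
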
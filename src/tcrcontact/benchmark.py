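"""The standard planted-contact recovery benchmark.

One call trains the head on a synthetic world's standard training draw
(400 positives at a 4:1 negative ratio) and measures, on a held-out draw
from the same world:

* discrimination — partial ROC-AUC at max FPR 0.1, computed within each
  epitope and averaged (the per-peptide protocol used for TCR specificity
  models, which also removes the per-epitope calibration offsets of the
  planted label rule from the ranking);
* explanation — mean Binding Region Hit Rate at t = 0.25 over the four
  directions of every positive test record, against the planted distances.

The same routine with ``signal_strength`` lowered toward zero traces the
degradation curve: both metrics should fall toward their chance levels
(0.5 and 0.25).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import unique_sequences
from .embeddings import build_store
from .evaluation import DIRECTIONS, brhr, partial_auc, residue_importance
from .synthetic import WorldConfig, generate_dataset, generate_world, synthetic_provider
from .training import TrainConfig, predict_dataset, train


@dataclass(frozen=True)
class BenchmarkProtocol:
    """Problem sizes and optimization settings of the standard run."""

    n_pos_train: int = 400
    n_pos_test: int = 100
    neg_ratio: float = 4.0
    epochs: int = 40
    batch_size: int = 128
    learning_rate: float = 3e-3
    dropout: float = 0.2
    tied: bool = True
    normalize_by_valid: bool = True
    brhr_t: float = 0.25
    max_fpr: float = 0.1


@dataclass
class BenchmarkResult:
    per_epitope_pauc: float
    pooled_pauc: float
    pooled_auc: float
    mean_brhr: float
    brhr_by_direction: dict
    mean_score_positive: float
    mean_score_negative: float
    n_train: int
    n_test: int
    history: list


def run_benchmark(world_config: WorldConfig, seed: int,
                  protocol: BenchmarkProtocol = BenchmarkProtocol(),
                  store_path=None) -> BenchmarkResult:
    """Generate → embed → train → evaluate, all reproducible from ``seed``."""
    import tempfile
    from pathlib import Path

    world = generate_world(world_config)
    train_ds = generate_dataset(world, n_pos=protocol.n_pos_train,
                                neg_ratio=protocol.neg_ratio,
                                seed=(seed * 1000 + 11) % (2 ** 31))
    test_ds = generate_dataset(world, n_pos=protocol.n_pos_test,
                               neg_ratio=protocol.neg_ratio,
                               seed=(seed * 1000 + 12) % (2 ** 31))
    provider = synthetic_provider(world)
    seqs = set(unique_sequences(train_ds.records))
    seqs |= set(unique_sequences(test_ds.records))
    if store_path is None:
        store_path = Path(tempfile.mkdtemp()) / "store.h5"
    store = build_store(sorted(seqs), provider, store_path)

    config = TrainConfig(epochs=protocol.epochs,
                         batch_size=protocol.batch_size,
                         learning_rate=protocol.learning_rate,
                         dropout=protocol.dropout, tied=protocol.tied,
                         normalize_by_valid=protocol.normalize_by_valid,
                         seed=seed % (2 ** 31), val_fraction=0.1)
    result = train(train_ds.records, store, config)

    preds = predict_dataset(test_ds.records, store, result.head)
    y = np.array([p.record.label for p in preds])
    scores = np.array([p.y_hat for p in preds])
    epitopes = np.array([p.record.epitope_id for p in preds])

    per_epi = []
    for e in sorted(set(epitopes)):
        m = epitopes == e
        if y[m].min() == y[m].max():
            continue
        per_epi.append(partial_auc(scores[m], y[m], protocol.max_fpr))

    rates = {d: [] for d in DIRECTIONS}
    for p, dmap in zip(preds, test_ds.distance_maps):
        if p.record.label != 1:
            continue
        for direction in DIRECTIONS:
            cmap = p.map_b if "cdr3a" in direction else p.map_a
            imp = residue_importance(cmap, direction)
            rates[direction].append(
                brhr(imp, dmap[direction], t=protocol.brhr_t).hit_rate)
    all_rates = [r for v in rates.values() for r in v]

    return BenchmarkResult(
        per_epitope_pauc=float(np.mean(per_epi)),
        pooled_pauc=float(partial_auc(scores, y, protocol.max_fpr)),
        pooled_auc=float(partial_auc(scores, y, 1.0)),
        mean_brhr=float(np.mean(all_rates)),
        brhr_by_direction={d: float(np.mean(v)) for d, v in rates.items()},
        mean_score_positive=float(scores[y == 1].mean()),
        mean_score_negative=float(scores[y == 0].mean()),
        n_train=len(train_ds.records), n_test=len(test_ds.records),
        history=result.history,
    )


def degradation_curve(seed: int, signal_grid=(0.0, 3.0, 10.0),
                      protocol: BenchmarkProtocol = BenchmarkProtocol(),
                      scale_down: float = 0.5) -> list:
    """Benchmark at decreasing signal strength (smaller runs per point).

    ``scale_down`` shrinks the training draw and epoch count for the grid
    points so the whole curve stays affordable; the relative ordering of the
    metrics is what matters here.
    """
    small = replace(protocol,
                    n_pos_train=int(protocol.n_pos_train * scale_down),
                    epochs=int(protocol.epochs * scale_down))
    out = []
    for s in signal_grid:
        cfg = WorldConfig(seed=seed % (2 ** 31), signal_strength=float(s))
        res = run_benchmark(cfg, seed=seed, protocol=small)
        out.append((float(s), res))
    return out
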
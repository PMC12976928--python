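"""The assembled prediction head: parameters, forward pass, checkpoint I/O."""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .autodiff import Tensor, parameter
from .embeddings import TriadBatch
from .layers import (ARROWS, MAP_A_AXES, MAP_B_AXES, AttentionParams,
                     ContactMap, ContactMapTensors, ThresholdBank, fuse,
                     predict)

#: softplus⁻¹(1): initializes the temperature τ at exactly 1.0
_TAU_RAW_INIT = math.log(math.e - 1.0)


@dataclass(frozen=True)
class HeadConfig:
    """Architecture hyperparameters (serialized next to every checkpoint)."""

    dimension: int
    max_length: int = 25
    n_thresholds: int = 10
    dropout: float = 0.2
    tied: bool = False                  # share weights across α/β-symmetric arrows
    normalize_by_valid: bool = False    # divide w by L₁·L₂ instead of N²
    value_init_scale: float = 0.05      # near-identity residual blocks at init
    init_seed: int = 0


class ContactHead:
    """Cross-attention fusion + contact-prototype head over embedding batches."""

    #: arrow pairs that share parameters in tied mode
    _TIED = {"ba": "ab", "e_ba": "e_ab", "ba_e": "ab_e"}

    def __init__(self, config: HeadConfig):
        self.config = config
        self.bank = ThresholdBank.evenly_spaced(config.n_thresholds)
        rng = np.random.default_rng(config.init_seed)
        self.arrows: dict[str, AttentionParams] = {}
        for name in ARROWS:
            if config.tied and name in self._TIED:
                self.arrows[name] = self.arrows[self._TIED[name]]
            else:
                self.arrows[name] = AttentionParams.init(
                    config.dimension, rng, value_scale=config.value_init_scale)
        self.tau_raw = parameter(_TAU_RAW_INIT)
        # logistic calibration of the contact score used by the training
        # objective: p = sigmoid(gain·ŷ + bias). ŷ is bounded well below 1 by
        # construction (A′ ≤ 1/|T| and the N² normalizer), so feeding it to
        # cross-entropy as a raw probability saturates the positive-class
        # gradient; the calibration is monotone in ŷ and leaves rankings,
        # contact maps, and reported scores untouched.
        self.cal_gain_raw = parameter(math.log(math.expm1(100.0)))
        self.cal_bias = parameter(-1.0)

    # ---- parameters -------------------------------------------------------

    @property
    def tau(self) -> Tensor:
        """Trainable temperature τ = softplus(tau_raw) > 0."""
        return self.tau_raw.softplus()

    def calibrate(self, y_hat: Tensor) -> Tensor:
        """Training-time probability p = σ(softplus(gain_raw)·ŷ + bias)."""
        return (self.cal_gain_raw.softplus() * y_hat + self.cal_bias).sigmoid()

    def named_parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {"tau_raw": self.tau_raw,
                                  "cal_gain_raw": self.cal_gain_raw,
                                  "cal_bias": self.cal_bias}
        seen = set()
        for name in ARROWS:
            p = self.arrows[name]
            if id(p) in seen:
                continue
            seen.add(id(p))
            for attr, t in zip(("wq", "wk", "wv", "bq", "bk", "bv",
                                "ln_gain", "ln_bias"), p.tensors()):
                out[f"{name}.{attr}"] = t
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def zero_grad(self) -> None:
        for t in self.parameters():
            t.zero_grad()

    # ---- forward ----------------------------------------------------------

    def forward(self, batch: TriadBatch, *, training: bool = False,
                rng: Optional[np.random.Generator] = None
                ) -> tuple[Tensor, ContactMapTensors, ContactMapTensors]:
        """Score a batch; returns (ŷ, α-side map, β-side map) as graph tensors."""
        dropout = self.config.dropout if training else 0.0
        fused = fuse(Tensor(batch.cdr3a), Tensor(batch.cdr3b),
                     Tensor(batch.peptide), batch.mask_a, batch.mask_b,
                     batch.mask_e, self.arrows, dropout=dropout, rng=rng)
        return predict(fused, self.tau, self.bank, self.config.max_length,
                       normalize_by_valid=self.config.normalize_by_valid)

    def predict_batch(self, batch: TriadBatch
                      ) -> tuple[np.ndarray, list[ContactMap], list[ContactMap]]:
        """Inference: ŷ per record plus concrete per-record contact maps."""
        y_hat, ta, tb = self.forward(batch, training=False)
        maps_a = _to_maps(ta, MAP_A_AXES, batch.mask_e, batch.mask_b)
        maps_b = _to_maps(tb, MAP_B_AXES, batch.mask_e, batch.mask_a)
        return y_hat.data.copy(), maps_a, maps_b

    # ---- checkpoints ------------------------------------------------------

    @staticmethod
    def _paths(path) -> tuple[Path, Path]:
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        return path, path.with_suffix(".json")

    def save(self, path) -> None:
        """Write parameters (.npz) plus a JSON sidecar with the config."""
        npz, sidecar_path = self._paths(path)
        arrays = {k: t.data for k, t in self.named_parameters().items()}
        np.savez(npz, **arrays)
        sidecar = {
            "config": asdict(self.config),
            "thresholds": self.bank.thresholds.tolist(),
            "format": 1,
        }
        sidecar_path.write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "ContactHead":
        npz, sidecar_path = cls._paths(path)
        sidecar = json.loads(sidecar_path.read_text())
        head = cls(HeadConfig(**sidecar["config"]))
        head.bank = ThresholdBank(np.asarray(sidecar["thresholds"]))
        with np.load(npz) as z:
            for k, t in head.named_parameters().items():
                t.data = z[k].astype(np.float64)
        return head


def _to_maps(t: ContactMapTensors, axes: tuple, row_mask: np.ndarray,
             col_mask: np.ndarray) -> list[ContactMap]:
    out = []
    filt = t.filters.data  # (|T|, B, N, N)
    for i in range(t.similarity.shape[0]):
        out.append(ContactMap(
            similarity=t.similarity.data[i].copy(),
            filters=filt[:, i].copy(),
            area=t.area.data[i].copy(),
            score=float(t.score.data[i]),
            row_axis=axes[0], col_axis=axes[1],
            row_length=int(row_mask[i].sum()),
            col_length=int(col_mask[i].sum()),
        ))
    return out
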
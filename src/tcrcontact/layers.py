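"""Cross-attention feature fusion and contact-prototype layers.

The head consumes three residue-embedding blocks — CDR3α (``E_a``), CDR3β
(``E_b``), peptide (``E_e``), each N×d with a validity mask — and produces a
binding probability together with residue-pair contact maps that *are* the
model's explanation, not a post-hoc readout.

Fusion wires six directed single-head cross-attentions:

    E_{a→b} = A(Q=E_a, K=V=E_b)        E_{b→a} = A(Q=E_b, K=V=E_a)
    E_{e→a→b} = A(Q=E_e, K=V=E_{a→b})  E_{a→b→e} = A(Q=E_{a→b}, K=V=E_e)
    E_{e→b→a} = A(Q=E_e, K=V=E_{b→a})  E_{b→a→e} = A(Q=E_{b→a}, K=V=E_e)

Each attention block applies learned Q/K/V projections, scaled dot-product
attention restricted to valid key positions, dropout, a residual connection
and layer normalization; padded query rows are zeroed on output.

The contact-prototype function f maps a pair of fused blocks to [0,1]:
cosine similarity (clamped to [0,1], divided by max(τ,1) with trainable
temperature τ) is pushed through a bank of soft threshold filters
M_i = σ((S − t_i)·N), aggregated as A′ = (1/|T|) Σ softmax(T)_i · M_i, and
summarized as w = ΣA′ / N². The final score averages the two chain-side w's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .autodiff import Tensor, constant, masked_softmax, parameter

_LN_EPS = 1e-5
_COS_EPS = 1e-12
_CLAMP_EPS = 1e-7


# ---------------------------------------------------------------------------
# threshold bank


@dataclass(frozen=True)
class ThresholdBank:
    """Fixed contact thresholds T and their softmax area weights A."""

    thresholds: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.thresholds, dtype=np.float64)
        object.__setattr__(self, "thresholds", t)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("thresholds must be a non-empty vector")
        if np.any(t < 0) or np.any(t > 1):
            raise ValueError("thresholds must lie in [0, 1]")
        if np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly increasing")

    @classmethod
    def evenly_spaced(cls, size: int = 10) -> "ThresholdBank":
        """t_i = i/(size+1) for i = 1..size."""
        i = np.arange(1, size + 1, dtype=np.float64)
        return cls(i / (size + 1))

    @property
    def area_weights(self) -> np.ndarray:
        """softmax(T); sums to 1, larger thresholds get larger weight."""
        e = np.exp(self.thresholds - self.thresholds.max())
        return e / e.sum()

    def __len__(self) -> int:
        return self.thresholds.size


# ---------------------------------------------------------------------------
# parameters


@dataclass
class AttentionParams:
    """Q/K/V projections plus layer-norm affine for one directed arrow."""

    wq: Tensor
    wk: Tensor
    wv: Tensor
    bq: Tensor
    bk: Tensor
    bv: Tensor
    ln_gain: Tensor
    ln_bias: Tensor

    @classmethod
    def init(cls, d: int, rng: np.random.Generator,
             value_scale: float = 0.05) -> "AttentionParams":
        """Glorot Q/K; the value path starts near zero (``value_scale`` ×
        Glorot) so each residual block opens close to the identity and the
        backbone's similarity structure survives to the prototype at the
        start of training."""
        scale = math.sqrt(2.0 / (d + d))
        mk = lambda s=scale: parameter(rng.normal(0.0, s, size=(d, d)))
        return cls(wq=mk(), wk=mk(), wv=mk(scale * value_scale),
                   bq=parameter(np.zeros(d)), bk=parameter(np.zeros(d)),
                   bv=parameter(np.zeros(d)),
                   ln_gain=parameter(np.ones(d)), ln_bias=parameter(np.zeros(d)))

    def tensors(self) -> list[Tensor]:
        return [self.wq, self.wk, self.wv, self.bq, self.bk, self.bv,
                self.ln_gain, self.ln_bias]


# ---------------------------------------------------------------------------
# building blocks


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = (var + _LN_EPS) ** -0.5
    return xc * inv * gain + bias


def cross_attend(query: Tensor, query_mask: np.ndarray, keyvalue: Tensor,
                 keyvalue_mask: np.ndarray, params: AttentionParams, *,
                 dropout: float = 0.0,
                 rng: Optional[np.random.Generator] = None) -> Tensor:
    """One directed cross-attention block: A(Q=query, K=V=keyvalue).

    Attention weights are a softmax over *valid* key positions only (padded
    keys get exactly zero weight); the block output is
    ``LayerNorm(query + Dropout(attention))`` with padded query rows zeroed.
    Shapes: (B, N, d) blocks, (B, N) masks.
    """
    if query.shape[-1] != keyvalue.shape[-1]:
        raise ValueError(
            f"embedding dims differ: {query.shape[-1]} vs {keyvalue.shape[-1]}")
    d = query.shape[-1]
    q = query @ params.wq + params.bq
    k = keyvalue @ params.wk + params.bk
    v = keyvalue @ params.wv + params.bv
    scores = (q @ k.swap_last()) * (1.0 / math.sqrt(d))
    attn = masked_softmax(scores, np.asarray(keyvalue_mask)[:, None, :])
    ctx = attn @ v
    if dropout > 0.0:
        if rng is None:
            raise ValueError("dropout requires an rng")
        keep = (rng.random(ctx.shape) >= dropout) / (1.0 - dropout)
        ctx = ctx * constant(keep)
    out = layer_norm(query + ctx, params.ln_gain, params.ln_bias)
    return out * constant(np.asarray(query_mask)[:, :, None])


@dataclass
class FusedEmbeddings:
    """The six fused blocks of the enhancement/fusion stage (batched)."""

    e_ab: Tensor      # α fused toward β, α-indexed rows
    e_ba: Tensor      # β fused toward α, β-indexed rows
    e_e_ab: Tensor    # peptide attending into E_{a→b}; peptide-indexed
    e_ab_e: Tensor    # E_{a→b} attending into peptide; α-indexed
    e_e_ba: Tensor    # peptide attending into E_{b→a}; peptide-indexed
    e_ba_e: Tensor    # E_{b→a} attending into peptide; β-indexed
    mask_a: np.ndarray
    mask_b: np.ndarray
    mask_e: np.ndarray


#: the six directed arrows, in wiring order
ARROWS = ("ab", "ba", "e_ab", "ab_e", "e_ba", "ba_e")


def fuse(ea: Tensor, eb: Tensor, ee: Tensor, mask_a: np.ndarray,
         mask_b: np.ndarray, mask_e: np.ndarray,
         params: dict, *, dropout: float = 0.0,
         rng: Optional[np.random.Generator] = None) -> FusedEmbeddings:
    """Run the full two-stage fusion; ``params`` maps arrow name → AttentionParams."""
    kw = dict(dropout=dropout, rng=rng)
    e_ab = cross_attend(ea, mask_a, eb, mask_b, params["ab"], **kw)
    e_ba = cross_attend(eb, mask_b, ea, mask_a, params["ba"], **kw)
    e_e_ab = cross_attend(ee, mask_e, e_ab, mask_a, params["e_ab"], **kw)
    e_ab_e = cross_attend(e_ab, mask_a, ee, mask_e, params["ab_e"], **kw)
    e_e_ba = cross_attend(ee, mask_e, e_ba, mask_b, params["e_ba"], **kw)
    e_ba_e = cross_attend(e_ba, mask_b, ee, mask_e, params["ba_e"], **kw)
    return FusedEmbeddings(e_ab=e_ab, e_ba=e_ba, e_e_ab=e_e_ab, e_ab_e=e_ab_e,
                           e_e_ba=e_e_ba, e_ba_e=e_ba_e,
                           mask_a=np.asarray(mask_a), mask_b=np.asarray(mask_b),
                           mask_e=np.asarray(mask_e))


# ---------------------------------------------------------------------------
# contact prototype


def similarity_map(e1: Tensor, e2: Tensor, tau: Tensor,
                   mask1: np.ndarray, mask2: np.ndarray) -> Tensor:
    """Pairwise residue similarity S ∈ [0,1]^{N×N}.

    S[k,j] = clamp(cos(e1_k, e2_j), 0, 1) / max(τ, 1). Negative cosines are
    clamped to 0 rather than rescaled so that orthogonal-or-opposed residue
    pairs read as "no contact", and the effective divisor is kept ≥ 1 so the
    stated [0,1] codomain holds for any trained τ. Zero-norm rows (padding,
    or degenerate embeddings) yield similarity 0. Padded rows/columns are
    zeroed exactly.
    """
    dots = e1 @ e2.swap_last()
    n1 = ((e1 * e1).sum(axis=-1, keepdims=True) + _COS_EPS) ** 0.5
    n2 = ((e2 * e2).sum(axis=-1, keepdims=True) + _COS_EPS) ** 0.5
    cos = dots / (n1 * n2.swap_last())
    s = cos.clamp(0.0, 1.0) / tau.maximum(1.0)
    pair = np.asarray(mask1)[..., :, None] * np.asarray(mask2)[..., None, :]
    return s * constant(pair)


def contact_filter(s: Tensor, t_i: float, n: int) -> Tensor:
    """Soft threshold filter M_i = σ((S − t_i)·N), a differentiable step."""
    return ((s - t_i) * float(n)).sigmoid()


def aggregate_area(filters: Sequence[Tensor], bank: ThresholdBank) -> Tensor:
    """A′ = (1/|T|) Σ_i softmax(T)_i · M_i."""
    if len(filters) != len(bank):
        raise ValueError(
            f"{len(filters)} filters but {len(bank)} thresholds")
    weights = bank.area_weights
    acc = filters[0] * float(weights[0])
    for m, a in zip(filters[1:], weights[1:]):
        acc = acc + m * float(a)
    return acc * (1.0 / len(bank))


def contact_score(area: Tensor, n: int) -> Tensor:
    """w = ΣA′ / N², the overall contact area relative to its maximum N²."""
    return area.sum(axis=(-2, -1)) * (1.0 / float(n) ** 2)


def _bank_area(s: Tensor, bank: ThresholdBank, slope: float
               ) -> tuple[Tensor, Tensor]:
    """All |T| filters and their weighted aggregate in one fused op.

    Computes M_i = σ((S − t_i)·slope) for every threshold and
    A′_raw = (1/|T|) Σ_i softmax(T)_i · M_i with an analytic backward
    dA′/dS = (slope/|T|) Σ_i softmax(T)_i · M_i(1−M_i). Numerically
    equivalent to composing :func:`contact_filter` and
    :func:`aggregate_area`; the stacked filters are returned as a
    constant tensor for inspection (gradients flow through the aggregate).
    """
    thr = bank.thresholds.reshape(-1, *([1] * s.ndim))
    wgt = bank.area_weights / len(bank)
    z = (s.data[None] - thr) * slope
    sig = 0.5 * (1.0 + np.tanh(0.5 * z))
    area = np.einsum("i,i...->...", wgt, sig)
    out = Tensor(area, s.requires_grad, (s,))

    def bw(g):
        deriv = np.einsum("i,i...->...", wgt, sig * (1.0 - sig)) * slope
        s._accumulate(g * deriv)

    out._backward = bw
    return Tensor(sig), out


@dataclass
class ContactMapTensors:
    """Autodiff-graph view of one prototype evaluation (batched)."""

    similarity: Tensor          # (B, N, N)
    filters: Tensor             # (|T|, B, N, N), stacked over thresholds
    area: Tensor                # (B, N, N)
    score: Tensor               # (B,)


def contact_prototype(e1: Tensor, e2: Tensor, tau: Tensor, bank: ThresholdBank,
                      mask1: np.ndarray, mask2: np.ndarray,
                      n: Optional[int] = None, *,
                      normalize_by_valid: bool = False) -> ContactMapTensors:
    """The full prototype function f(E1, E2) → w with all intermediates.

    ``n`` defaults to the padded length N and sets both the filter slope and
    the w normalizer (N²). With ``normalize_by_valid`` the score divides by
    L₁·L₂ instead of N² (off by default; N² is the defined maximum area).

    All |T| filters are evaluated in one broadcast over a leading threshold
    axis; numerically equivalent to applying :func:`contact_filter` and
    :func:`aggregate_area` per threshold.
    """
    if n is None:
        n = e1.shape[-2]
    s = similarity_map(e1, e2, tau, mask1, mask2)
    filters, area_raw = _bank_area(s, bank, float(n))
    pair = np.asarray(mask1)[..., :, None] * np.asarray(mask2)[..., None, :]
    area = area_raw * constant(pair)
    if normalize_by_valid:
        l1 = np.asarray(mask1).sum(-1)
        l2 = np.asarray(mask2).sum(-1)
        denom = np.maximum(l1 * l2, 1.0)
        w = area.sum(axis=(-2, -1)) * constant(1.0 / denom)
    else:
        w = contact_score(area, n)
    return ContactMapTensors(similarity=s, filters=filters, area=area, score=w)


@dataclass(frozen=True)
class ContactMap:
    """Concrete (numpy) contact map for one record; the explanation object."""

    similarity: np.ndarray      # (N, N)
    filters: np.ndarray         # (|T|, N, N)
    area: np.ndarray            # (N, N) — A′
    score: float                # w
    row_axis: str               # sequence type indexing the rows
    col_axis: str
    row_length: int
    col_length: int


def predict(fused: FusedEmbeddings, tau: Tensor, bank: ThresholdBank,
            n: Optional[int] = None, *, normalize_by_valid: bool = False
            ) -> tuple[Tensor, ContactMapTensors, ContactMapTensors]:
    """Score a batch: w_{a,e} = f(E_{e→b→a}, E_{b→a→e}),
    w_{b,e} = f(E_{e→a→b}, E_{a→b→e}), ŷ = (w_{a,e} + w_{b,e})/2.

    Note the axis bookkeeping: the α-side map pairs a peptide-indexed block
    with a β-indexed block (its *content* flows through the β→α arrow whose
    values are E_a), so its rows are peptide positions and its columns CDR3β
    positions; symmetrically the β-side map's columns are CDR3α positions.
    """
    kw = dict(n=n, normalize_by_valid=normalize_by_valid)
    map_a = contact_prototype(fused.e_e_ba, fused.e_ba_e, tau, bank,
                              fused.mask_e, fused.mask_b, **kw)
    map_b = contact_prototype(fused.e_e_ab, fused.e_ab_e, tau, bank,
                              fused.mask_e, fused.mask_a, **kw)
    y_hat = (map_a.score + map_b.score) * 0.5
    return y_hat, map_a, map_b


#: axis labels of the two maps returned by :func:`predict`
MAP_A_AXES = ("peptide", "cdr3b")
MAP_B_AXES = ("peptide", "cdr3a")


def bce_loss(y_hat: Tensor, y: np.ndarray, pos_weight: float = 1.0) -> Tensor:
    """Class-weighted binary cross-entropy on the probability-like score ŷ.

    L = mean over the batch of −[pos_weight·y·log ŷ + (1−y)·log(1−ŷ)], with
    ŷ clamped to [1e−7, 1−1e−7].
    """
    if pos_weight <= 0:
        raise ValueError("pos_weight must be positive")
    y = np.asarray(y, dtype=np.float64)
    yh = y_hat.clamp(_CLAMP_EPS, 1.0 - _CLAMP_EPS)
    term = yh.log() * constant(pos_weight * y) + (1.0 - yh).log() * constant(1.0 - y)
    return -(term.mean())
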